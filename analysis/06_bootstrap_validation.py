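#!/usr/bin/env python
"""Bootstrap internal validation of the whole-model statistic.

1,000 unstratified case resamples of the cohort; each is refitted and
the whole-model LR chi-square recorded.  The 95% percentile interval of
the resampled statistics describes the range of probable population
values; the observed statistic should lie inside it.  Writes
results/bootstrap.json.

Usage: python analysis/06_bootstrap_validation.py [seed]
"""

import json
import sys
from pathlib import Path

import mews_eval as me

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0

cohort = me.reference_cohort()
fit = me.fit_logistic(cohort)
observed, _ = me.whole_model_test(fit)
result = me.bootstrap_whole_model(cohort, n_resamples=1000, seed=seed)
lo, hi = result.percentile_interval

print(f"observed whole-model chi-square: {observed:.4f}")
print(f"bootstrap (1,000 cycles, seed {seed}): 95% percentile interval "
      f"{lo:.2f} to {hi:.2f}; {result.n_failed} failed resamples")
inside = lo <= observed <= hi
print("observed statistic is "
      + ("inside" if inside else "OUTSIDE") + " the interval")

payload = result.to_json()
payload["observed_chi_square"] = observed
payload["observed_within_interval"] = inside
with (OUT / "bootstrap.json").open("w") as fh:
    json.dump(payload, fh, indent=2, sort_keys=True)
    fh.write("\n")
print(f"wrote {OUT / 'bootstrap.json'}")
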