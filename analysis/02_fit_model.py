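#!/usr/bin/env python
"""Fit the univariable logistic model of mortality on MEWS.

Reports the whole-model likelihood-ratio chi-square, the per-unit odds
ratio, the C-index, and the fitted mortality probability at every
observed score; writes results/model_summary.json.
"""

import json
from pathlib import Path

import mews_eval as me

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cohort = me.reference_cohort()
fit = me.fit_logistic(cohort)
summary = me.model_summary(fit, cohort)

print(f"logit Pr(death) = {fit.beta0:.4f} + {fit.beta1:.4f} * MEWS "
      f"(converged in {fit.n_iter} Newton steps)")
print(f"whole-model LR chi-square = {summary.chi_square:.4f} "
      f"(df=1, P = {summary.p_value:.4f})")
print(f"odds ratio per unit = {summary.odds_ratio_per_unit:.4f} "
      f"(95% CI {summary.or_ci[0]:.2f} to {summary.or_ci[1]:.2f})")
print(f"C-index = {summary.c_index:.4f} "
      f"(95% CI {summary.c_index_ci[0]:.2f} to {summary.c_index_ci[1]:.2f})")
print("fitted mortality probability by score:")
for s, p in summary.fitted_probability.items():
    print(f"  MEWS {s}: {100 * p:.1f}%")

payload = {**summary.to_json(), "beta0": fit.beta0, "beta1": fit.beta1}
with (OUT / "model_summary.json").open("w") as fh:
    json.dump(payload, fh, indent=2, sort_keys=True)
    fh.write("\n")
print(f"wrote {OUT / 'model_summary.json'}")
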