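#!/usr/bin/env python
"""Reconstruct the per-patient cohort from the packaged cumulative table.

The published evaluation prints, for every MEWS threshold T, the
cross-classification of "predict death iff score >= T".  Because the TP
and FP columns cumulate the per-score outcome counts from the top score
down, first differencing recovers the exact per-score distribution and
hence the full 263-patient cohort.  Writes the cohort and the per-score
counts under results/ and prints the mortality incidence.
"""

from pathlib import Path

import mews_eval as me

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

table = me.load_reference_table()
counts = me.invert_cumulative_table(table)
cohort = me.expand_to_cohort(counts)

me.cohort.write_counts_csv(counts, OUT / "score_counts.csv")
me.write_cohort_csv(cohort, OUT / "cohort.csv")

lo, hi = me.proportion_ci(cohort.n_deceased, cohort.n)
print(f"cohort reconstructed: n={cohort.n}, deceased={cohort.n_deceased}, "
      f"alive={cohort.n_alive}")
print("per-score deaths:   ", dict(enumerate(counts.deaths)))
print("per-score survivors:", dict(enumerate(counts.survivors)))
print(f"mortality incidence {100 * cohort.n_deceased / cohort.n:.1f}% "
      f"(95% CI {100 * lo:.1f}% to {100 * hi:.1f}%)")

# round-trip check: re-cumulating the counts reproduces the table exactly
assert me.cumulate_counts(counts) == table
print("forward re-cumulation reproduces the input table exactly")
print(f"wrote {OUT / 'cohort.csv'} and {OUT / 'score_counts.csv'}")
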