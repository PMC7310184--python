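#!/usr/bin/env python
"""Scan every score threshold and select the optimal cut-point.

For each threshold T the rule "predict death iff MEWS >= T" yields a 2x2
classification; the scan tabulates sensitivity, 1-specificity and their
difference, and the cut-point maximizing that difference (the Youden
criterion) is starred.  Writes results/threshold_scan.csv.
"""

from pathlib import Path

import mews_eval as me

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cohort = me.reference_cohort()
scan = me.threshold_scan(cohort)
cut, diff = me.select_cutpoint(scan)

print(f"{'T':>2} {'sens%':>6} {'1-spec%':>8} {'diff%':>6} {'TP':>4} {'TN':>4} "
      f"{'FP':>4} {'FN':>4}")
for r in scan:
    star = "*" if r.threshold == cut else " "
    print(f"{r.threshold:>2} {r.sensitivity_pct:>6.1f} "
          f"{r.one_minus_specificity_pct:>8.1f} {r.youden_diff_pct:>5.1f}{star} "
          f"{r.tp:>4} {r.tn:>4} {r.fp:>4} {r.fn:>4}")
print(f"selected cut-point: MEWS >= {cut} "
      f"(sensitivity - (1-specificity) = {diff:.1f}%)")

me.thresholds.write_scan_csv(scan, OUT / "threshold_scan.csv", starred_threshold=cut)
print(f"wrote {OUT / 'threshold_scan.csv'}")
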