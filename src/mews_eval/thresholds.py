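"""Threshold classification, cut-point selection, and dichotomized models.

Everything here classifies with the rule "predict death iff MEWS >= T"
(deceased-positive orientation) except ``classification_at_probability``,
which applies a cut on the fitted mortality probability of a logistic
model and reports the matrix in an alive-positive orientation — the
orientation some published ledgers use, with survival as the "positive"
prognosis.  Orientation is always explicit on the matrix.

Cut-point selection maximizes sensitivity - (1 - specificity) over the
threshold scan (the Youden criterion on the percentage scale); ties break
toward the higher, more specific threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import chi2 as _chi2

from .cohort import Cohort
from .errors import DegenerateDataError
from .logistic import LogisticFit, predicted_probability
from .metrics import ConfusionMatrix, Estimate, proportion_ci, ratio_ci

__all__ = [
    "ThresholdScanRow",
    "DichotomizedSummary",
    "classification_at_threshold",
    "threshold_scan",
    "select_cutpoint",
    "classification_at_probability",
    "dichotomized_model",
    "write_scan_csv",
]


@dataclass(frozen=True)
class ThresholdScanRow:
    """One row of the threshold scan, percentages at full precision."""

    threshold: int
    sensitivity_pct: float
    one_minus_specificity_pct: float
    youden_diff_pct: float  # sensitivity - (1 - specificity)
    tp: int
    tn: int
    fp: int
    fn: int


def classification_at_threshold(cohort: Cohort, threshold: int) -> ConfusionMatrix:
    """2x2 counts of "predict death iff score >= threshold", deceased positive."""
    if cohort.n == 0:
        raise DegenerateDataError("empty cohort")
    scores = cohort.scores
    deceased = cohort.outcomes == 1
    predicted = scores >= threshold
    return ConfusionMatrix(
        a=int(np.sum(predicted & deceased)),
        b=int(np.sum(predicted & ~deceased)),
        c=int(np.sum(~predicted & deceased)),
        d=int(np.sum(~predicted & ~deceased)),
        positive_label="deceased",
        negative_label="alive",
    )


def threshold_scan(cohort: Cohort) -> list[ThresholdScanRow]:
    """Scan every threshold from the maximum observed score down to 0."""
    if cohort.n == 0:
        raise DegenerateDataError("empty cohort")
    if cohort.n_deceased == 0 or cohort.n_alive == 0:
        raise DegenerateDataError("both outcome classes required for a scan")
    rows = []
    for t in range(int(cohort.scores.max()), -1, -1):
        m = classification_at_threshold(cohort, t)
        sens = 100.0 * m.a / m.c1
        fpr = 100.0 * m.b / m.c2
        rows.append(
            ThresholdScanRow(
                threshold=t,
                sensitivity_pct=sens,
                one_minus_specificity_pct=fpr,
                youden_diff_pct=sens - fpr,
                tp=m.a, tn=m.d, fp=m.b, fn=m.c,
            )
        )
    return rows


def select_cutpoint(scan: list[ThresholdScanRow]) -> tuple[int, float]:
    """Threshold maximizing sensitivity - (1-specificity); ties -> higher
    threshold (the more specific rule).  Returns (threshold, difference %)."""
    if not scan:
        raise ValueError("empty scan")
    best = max(scan, key=lambda r: (r.youden_diff_pct, r.threshold))
    return best.threshold, best.youden_diff_pct


def classification_at_probability(
    fit: LogisticFit, cohort: Cohort, p_cut: float = 0.5
) -> ConfusionMatrix:
    """Classify by fitted mortality probability: predict death iff
    Pr(death | score) > p_cut.

    The matrix is reported in the alive-positive orientation (rows:
    predicted alive first; columns: actual alive first), i.e. a = predicted
    alive & alive, b = predicted alive & deceased, c = predicted deceased &
    alive, d = predicted deceased & deceased.
    """
    if cohort.n == 0:
        raise DegenerateDataError("empty cohort")
    probs = np.array([predicted_probability(fit, int(s)) for s in cohort.scores])
    predicted_dead = probs > p_cut
    deceased = cohort.outcomes == 1
    return ConfusionMatrix(
        a=int(np.sum(~predicted_dead & ~deceased)),
        b=int(np.sum(~predicted_dead & deceased)),
        c=int(np.sum(predicted_dead & ~deceased)),
        d=int(np.sum(predicted_dead & deceased)),
        positive_label="alive",
        negative_label="deceased",
    )


@dataclass(frozen=True)
class DichotomizedSummary:
    """The cut-point model: 2x2 exposure-by-death table and its effect sizes."""

    cutpoint: int
    matrix: ConfusionMatrix  # deceased-positive, exposure = score >= cutpoint
    odds_ratio: Estimate
    relative_risk: Estimate
    chi_square: float
    p_value: float
    misclassification: Estimate

    def to_json(self) -> dict:
        return {
            "cutpoint": self.cutpoint,
            "matrix": self.matrix.to_json(),
            "odds_ratio": self.odds_ratio.to_json(),
            "relative_risk": self.relative_risk.to_json(),
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "misclassification": self.misclassification.to_json(),
        }


def dichotomized_model(
    cohort: Cohort, cutpoint: int, level: float = 0.95
) -> DichotomizedSummary:
    """Collapse the score to the indicator [score >= cutpoint] and summarize.

    Odds ratio is the cross-product (tp*tn)/(fp*fn); relative risk compares
    death risk above versus below the cut; the chi-square is the whole-model
    LR statistic of the logistic fit on the binary indicator (identical null
    model to the full fit); misclassification is (fp+fn)/t under "predict
    death iff score >= cutpoint", with a Wilson interval.
    """
    m = classification_at_threshold(cohort, cutpoint)
    if m.r1 == 0 or m.r2 == 0:
        raise DegenerateDataError(
            f"both exposure groups must be non-empty at cutpoint {cutpoint}"
        )
    zero_cell = min(m.a, m.b, m.c, m.d) == 0

    if zero_cell:
        or_est = Estimate(float("inf") if m.a * m.d > 0 else 0.0,
                          *ratio_ci(m, "odds_ratio", level)[:2],
                          note="zero cell: 0.5 continuity correction applied to the interval")
    else:
        or_lo, or_hi, _ = ratio_ci(m, "odds_ratio", level)
        or_est = Estimate((m.a * m.d) / (m.b * m.c), or_lo, or_hi)

    if m.c == 0:
        rr_est = Estimate(float("inf"),
                          *ratio_ci(m, "relative_risk", level)[:2],
                          note="zero cell: 0.5 continuity correction applied to the interval")
    else:
        rr_lo, rr_hi, corrected = ratio_ci(m, "relative_risk", level)
        rr_est = Estimate(
            (m.a / m.r1) / (m.c / m.r2), rr_lo, rr_hi,
            note="zero cell: 0.5 continuity correction applied to the interval"
            if corrected else None,
        )

    # The logistic model on the binary indicator is saturated, so its
    # maximized log-likelihood has the closed form sum_g [d ln(d/n) +
    # (n-d) ln(1-d/n)] over the two exposure groups (0 ln 0 = 0); this is the
    # limit of the Newton fit and stays defined when a cell is zero.
    def _binll(d: int, n: int) -> float:
        out = 0.0
        if 0 < d:
            out += d * np.log(d / n)
        if d < n:
            out += (n - d) * np.log(1 - d / n)
        return out

    loglik_full = _binll(m.a, m.r1) + _binll(m.c, m.r2)
    loglik_null = _binll(m.c1, m.t)
    stat = max(0.0, 2.0 * (loglik_full - loglik_null))
    p = float(_chi2.sf(stat, df=1))

    k = m.b + m.c
    mis_lo, mis_hi = proportion_ci(k, m.t, level)
    mis = Estimate(k / m.t, mis_lo, mis_hi)

    return DichotomizedSummary(
        cutpoint=cutpoint,
        matrix=m,
        odds_ratio=or_est,
        relative_risk=rr_est,
        chi_square=stat,
        p_value=p,
        misclassification=mis,
    )


def write_scan_csv(
    scan: list[ThresholdScanRow],
    path: str | Path,
    starred_threshold: int | None = None,
) -> None:
    """Write the scan with percentages rounded to 1 decimal; the selected
    cut-point's difference column is starred, mirroring the published layout."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "threshold", "sensitivity_pct", "one_minus_specificity_pct",
            "sensitivity_minus_one_minus_specificity_pct",
            "tp", "tn", "fp", "fn",
        ])
        for r in scan:
            diff = f"{r.youden_diff_pct:.1f}"
            if starred_threshold is not None and r.threshold == starred_threshold:
                diff += "*"
            writer.writerow([
                r.threshold,
                f"{r.sensitivity_pct:.1f}",
                f"{r.one_minus_specificity_pct:.1f}",
                diff,
                r.tp, r.tn, r.fp, r.fn,
            ])
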