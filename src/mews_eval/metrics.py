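"""Complete diagnostic-accuracy ledger for an oriented 2x2 confusion matrix.

Cell layout (rows = predicted class, columns = actual class, positive
class first):

    =============  ==============  ==============  =======
    predicted      actual positive actual negative margin
    =============  ==============  ==============  =======
    positive       a (TP)          b (FP)          r1
    negative       c (FN)          d (TN)          r2
    margin         c1              c2              t
    =============  ==============  ==============  =======

``metric_report`` evaluates every standard metric directly from these
cells: prevalences, accuracy and misclassification rate, sensitivity and
specificity, predictive values, likelihood ratios, cross-product odds
ratio, relative risk, diagnostic and error odds ratios, difference in
proportions / absolute and relative risk reduction, number needed to
treat, Youden J and number needed to diagnose, number needed to
misdiagnose, and Cohen's kappa — each with a 95% interval.

Interval methods (point estimates are the scientific content; interval
choices are this package's): Wilson score for simple proportions,
log-scale delta method for ratio measures, Wald for differences, an
asymptotic standard error for kappa, and inversion of the parent interval
for the reciprocal measures (NNT/NND/NNM), where a parent interval
crossing zero gives an infinite bound.  Metrics with a zero denominator
are reported as non-finite with a reason, never dropped; a zero cell in a
ratio triggers the Haldane-Anscombe 0.5 correction for the interval only,
flagged in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.stats import norm

__all__ = [
    "ConfusionMatrix",
    "Estimate",
    "MetricReport",
    "metric_report",
    "cohen_kappa",
    "proportion_ci",
    "ratio_ci",
    "report_markdown",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Oriented 2x2 counts; ``positive_label`` names the positive class."""

    a: int
    b: int
    c: int
    d: int
    positive_label: str = "deceased"
    negative_label: str = "alive"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    # margins, in the ledger's notation
    @property
    def r1(self) -> int:
        return self.a + self.b

    @property
    def r2(self) -> int:
        return self.c + self.d

    @property
    def c1(self) -> int:
        return self.a + self.c

    @property
    def c2(self) -> int:
        return self.b + self.d

    @property
    def t(self) -> int:
        return self.r1 + self.r2

    def swap_orientation(self) -> "ConfusionMatrix":
        """Relabel the negative class as positive (180-degree cell rotation)."""
        return ConfusionMatrix(
            a=self.d, b=self.c, c=self.b, d=self.a,
            positive_label=self.negative_label,
            negative_label=self.positive_label,
        )

    def transpose(self) -> "ConfusionMatrix":
        """Swap the predicted/actual axes (b <-> c)."""
        return ConfusionMatrix(
            a=self.a, b=self.c, c=self.b, d=self.d,
            positive_label=self.positive_label,
            negative_label=self.negative_label,
        )

    def to_json(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "r1": self.r1, "r2": self.r2, "c1": self.c1, "c2": self.c2,
            "t": self.t,
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
        }


@dataclass(frozen=True)
class Estimate:
    """A point estimate with an optional interval and annotation."""

    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    note: str | None = None

    def to_json(self) -> dict:
        def enc(x):
            if x is None:
                return None
            if math.isinf(x):
                return "+inf" if x > 0 else "-inf"
            if math.isnan(x):
                return "undefined"
            return x

        out = {"value": enc(self.value), "ci_low": enc(self.ci_low), "ci_high": enc(self.ci_high)}
        if self.note:
            out["note"] = self.note
        return out


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    z = norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return max(0.0, centre - half), min(1.0, centre + half)


def _wald_interval(est: float, se: float, level: float) -> tuple[float, float]:
    z = norm.ppf(0.5 + level / 2)
    return est - z * se, est + z * se


def ratio_ci(
    m: ConfusionMatrix,
    which: str,
    level: float = 0.95,
) -> tuple[float, float, bool]:
    """Log-scale delta-method interval for a ratio measure.

    ``which`` is one of odds_ratio, relative_risk, lr_positive, lr_negative.
    Returns (low, high, corrected); ``corrected`` is True when a zero cell
    forced the Haldane-Anscombe 0.5 continuity correction (applied to all
    four cells, interval only).
    """
    a, b, c, d = m.a, m.b, m.c, m.d
    corrected = False
    if which in ("odds_ratio",) and min(a, b, c, d) == 0:
        corrected = True
    if which == "relative_risk" and (a == 0 or c == 0 or m.r1 == 0 or m.r2 == 0):
        corrected = True
    if which == "lr_positive" and (a == 0 or b == 0):
        corrected = True
    if which == "lr_negative" and (c == 0 or d == 0):
        corrected = True
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if which == "odds_ratio":
        log_est = math.log((a * d) / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    elif which == "relative_risk":
        log_est = math.log((a / r1) / (c / r2))
        se = math.sqrt(1 / a - 1 / r1 + 1 / c - 1 / r2)
    elif which == "lr_positive":
        # LR+ = (a/c1)/(b/c2)
        log_est = math.log((a / c1) / (b / c2))
        se = math.sqrt(1 / a - 1 / c1 + 1 / b - 1 / c2)
    elif which == "lr_negative":
        # LR- = (c/c1)/(d/c2)
        log_est = math.log((c / c1) / (d / c2))
        se = math.sqrt(1 / c - 1 / c1 + 1 / d - 1 / c2)
    else:
        raise ValueError(f"unknown ratio {which!r}")
    lo, hi = _wald_interval(log_est, se, level)
    return math.exp(lo), math.exp(hi), corrected


def cohen_kappa(m: ConfusionMatrix, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa: (p_o - p_e)/(1 - p_e) with chance agreement from the
    margin products; asymptotic interval kappa +/- z*sqrt(p_o(1-p_o)/(n(1-p_e)^2))."""
    if m.t < 2:
        raise ValueError("kappa needs at least 2 observations")
    t = m.t
    p_o = (m.a + m.d) / t
    p_e = (m.r1 * m.c1 + m.r2 * m.c2) / (t * t)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else float("nan"), (float("nan"), float("nan"))
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / (t * (1 - p_e) ** 2))
    lo, hi = _wald_interval(kappa, se, level)
    return kappa, (max(-1.0, lo), min(1.0, hi))


@dataclass(frozen=True)
class MetricReport:
    matrix: ConfusionMatrix
    prevalence_positive: Estimate
    prevalence_negative: Estimate
    accuracy: Estimate
    misclassification_rate: Estimate
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    lr_positive: Estimate
    lr_negative: Estimate
    odds_ratio: Estimate
    relative_risk: Estimate
    diagnostic_odds_ratio: Estimate
    error_odds_ratio: Estimate
    difference_in_proportions: Estimate
    nnt: Estimate
    arr: Estimate
    rrr: Estimate
    youden_j: Estimate
    nnd: Estimate
    nnm: Estimate
    kappa: Estimate

    def to_json(self) -> dict:
        out: dict = {"matrix": self.matrix.to_json()}
        for f in fields(self):
            if f.name == "matrix":
                continue
            out[f.name] = getattr(self, f.name).to_json()
        return out


def _safe_div(num: float, den: float, reason: str) -> tuple[float, str | None]:
    if den == 0:
        return (float("inf") if num > 0 else float("nan")), reason
    return num / den, None


def metric_report(m: ConfusionMatrix, level: float = 0.95) -> MetricReport:
    """Evaluate the full metric ledger on one oriented matrix."""
    if m.t < 1:
        raise ValueError("empty matrix")
    a, b, c, d, t = m.a, m.b, m.c, m.d, m.t
    r1, r2, c1, c2 = m.r1, m.r2, m.c1, m.c2
    z = norm.ppf(0.5 + level / 2)

    def prop(k: int, n: int, reason: str) -> Estimate:
        if n == 0:
            return Estimate(float("nan"), note=reason)
        lo, hi = proportion_ci(k, n, level)
        return Estimate(k / n, lo, hi)

    prev_pos = prop(c1, t, "empty matrix")
    prev_neg = prop(c2, t, "empty matrix")
    acc = prop(a + d, t, "empty matrix")
    misclass = prop(b + c, t, "empty matrix")
    sens = prop(a, c1, "no actual-positive cases")
    spec = prop(d, c2, "no actual-negative cases")
    ppv = prop(a, r1, "no predicted-positive cases")
    npv = prop(d, r2, "no predicted-negative cases")

    def ratio(which: str, value: float, undefined: str | None) -> Estimate:
        if undefined is not None:
            return Estimate(value, note=undefined)
        lo, hi, corrected = ratio_ci(m, which, level)
        return Estimate(
            value, lo, hi,
            note="zero cell: 0.5 continuity correction applied to the interval"
            if corrected else None,
        )

    se_v, se_note = _safe_div(a, c1, "sensitivity undefined")
    sp_v, sp_note = _safe_div(d, c2, "specificity undefined")

    lrp_v, lrp_note = _safe_div(se_v, 1 - sp_v, "specificity is 1: LR+ denominator zero")
    lrn_v, lrn_note = _safe_div(1 - se_v, sp_v, "specificity is 0: LR- denominator zero")
    lrp = ratio("lr_positive", lrp_v, se_note or sp_note or lrp_note)
    lrn = ratio("lr_negative", lrn_v, se_note or sp_note or lrn_note)

    or_v, or_note = _safe_div(a * d, b * c, "zero cell: odds ratio unbounded")
    odds = ratio("odds_ratio", or_v, or_note)

    if r1 == 0 or r2 == 0:
        rr = Estimate(float("nan"), note="a predicted-class margin is zero")
        dp = Estimate(float("nan"), note="a predicted-class margin is zero")
    else:
        p1, p2 = a / r1, c / r2
        rr_v, rr_note = _safe_div(p1, p2, "no false negatives: relative risk unbounded")
        rr = ratio("relative_risk", rr_v, rr_note)
        dp_se = math.sqrt(p1 * (1 - p1) / r1 + p2 * (1 - p2) / r2)
        dp_lo, dp_hi = _wald_interval(p1 - p2, dp_se, level)
        dp = Estimate(p1 - p2, dp_lo, dp_hi)

    # DOR and EOR from the ledger's sensitivity/specificity formulas.
    dor_v, dor_note = _safe_div(
        se_v / (1 - se_v) if se_v != 1 else float("inf"),
        (1 - sp_v) / sp_v if sp_v != 0 else float("inf"),
        "degenerate sensitivity/specificity",
    )
    if se_v == 1 or sp_v == 1:
        dor_v, dor_note = float("inf"), "perfect sensitivity or specificity"
    dor = Estimate(dor_v, *ratio_ci(m, "odds_ratio", level)[:2]) if dor_note is None \
        else Estimate(dor_v, note=dor_note)

    if se_v == 1 or sp_v in (0.0, 1.0):
        eor = Estimate(float("inf"), note="degenerate sensitivity/specificity")
    else:
        eor_v = (se_v / (1 - se_v)) / (sp_v / (1 - sp_v))
        # identical log-variance structure to the cross-product OR of the
        # transposed comparison; report the delta interval on its own scale
        se_log = math.sqrt(
            sum(1 / x for x in (a, c, b, d) if x > 0)
        )
        lo, hi = _wald_interval(math.log(eor_v), se_log, level)
        eor = Estimate(eor_v, math.exp(lo), math.exp(hi))

    # Reciprocal measures: invert the parent interval; a parent interval
    # crossing zero yields an infinite bound, reported explicitly.
    def reciprocal(parent: Estimate, reason: str) -> Estimate:
        v = parent.value
        if not math.isfinite(v) or v == 0:
            return Estimate(float("inf"), note=reason)
        est = 1 / abs(v)
        lo_p, hi_p = parent.ci_low, parent.ci_high
        if lo_p is None or hi_p is None:
            return Estimate(est)
        # parent CI is on the signed scale; the reciprocal's bounds come from
        # the bound magnitudes, infinite when the parent CI crosses zero
        same_sign = [x for x in (lo_p, hi_p) if x * v > 0]
        opposite = [x for x in (lo_p, hi_p) if x * v <= 0]
        lo_r = 1 / max(abs(x) for x in (lo_p, hi_p))
        hi_r = 1 / min(abs(x) for x in same_sign) if not opposite else float("inf")
        note = "interval unbounded: parent interval crosses zero" if opposite else None
        return Estimate(est, lo_r, hi_r, note=note)

    youden_v = se_v + sp_v - 1
    if se_note or sp_note:
        youden = Estimate(float("nan"), note=se_note or sp_note)
    else:
        y_se = math.sqrt(
            se_v * (1 - se_v) / c1 + sp_v * (1 - sp_v) / c2
        )
        y_lo, y_hi = _wald_interval(youden_v, y_se, level)
        youden = Estimate(youden_v, y_lo, y_hi)

    nnt = reciprocal(dp, "difference in proportions is zero or undefined")
    nnd = reciprocal(youden, "Youden J is zero or undefined")

    arr = Estimate(
        -dp.value,
        None if dp.ci_high is None else -dp.ci_high,
        None if dp.ci_low is None else -dp.ci_low,
        note=dp.note,
    )
    if r2 == 0 or c == 0:
        rrr = Estimate(float("nan"), note="baseline risk c/r2 is zero or undefined")
    else:
        base = c / r2
        rrr = Estimate(
            arr.value / base,
            None if arr.ci_low is None else arr.ci_low / base,
            None if arr.ci_high is None else arr.ci_high / base,
        )

    if misclass.value == 0:
        nnm = Estimate(float("inf"), note="perfect accuracy: no misclassifications")
    else:
        nnm = Estimate(
            1 / misclass.value,
            1 / misclass.ci_high if misclass.ci_high else float("inf"),
            1 / misclass.ci_low if misclass.ci_low else float("inf"),
        )

    k_v, (k_lo, k_hi) = cohen_kappa(m, level)
    kap = Estimate(k_v, k_lo, k_hi)

    return MetricReport(
        matrix=m,
        prevalence_positive=prev_pos,
        prevalence_negative=prev_neg,
        accuracy=acc,
        misclassification_rate=misclass,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_positive=lrp,
        lr_negative=lrn,
        odds_ratio=odds,
        relative_risk=rr,
        diagnostic_odds_ratio=dor,
        error_odds_ratio=eor,
        difference_in_proportions=dp,
        nnt=nnt,
        arr=arr,
        rrr=rrr,
        youden_j=youden,
        nnd=nnd,
        nnm=nnm,
        kappa=kap,
    )


# display rounding: 3 decimals for proportion-type metrics, 2 for ratios
_PROPORTIONS = {
    "prevalence_positive", "prevalence_negative", "accuracy",
    "misclassification_rate", "sensitivity", "specificity", "ppv", "npv",
    "difference_in_proportions", "arr", "youden_j", "kappa",
}


def _fmt(x: float | None, nd: int) -> str:
    if x is None:
        return ""
    if math.isinf(x):
        return "infinite" if x > 0 else "-infinite"
    if math.isnan(x):
        return "undefined"
    return f"{x:.{nd}f}"


def report_markdown(report: MetricReport) -> str:
    """Render the ledger as a Markdown block mirroring the published layout."""
    m = report.matrix
    pos, neg = m.positive_label, m.negative_label
    lines = [
        f"| Predicted \\ Actual | {pos} | {neg} | Totals |",
        "|---|---|---|---|",
        f"| {pos} | {m.a} (a or TP) | {m.b} (b or FP) | {m.r1} (r1) |",
        f"| {neg} | {m.c} (c or FN) | {m.d} (d or TN) | {m.r2} (r2) |",
        f"| **Totals** | {m.c1} (c1) | {m.c2} (c2) | {m.t} (t) |",
        "",
        "| Metric | Estimate | 95% CI |",
        "|---|---|---|",
    ]
    for f in fields(report):
        if f.name == "matrix":
            continue
        est: Estimate = getattr(report, f.name)
        nd = 3 if f.name in _PROPORTIONS else 2
        ci = ""
        if est.ci_low is not None or est.ci_high is not None:
            ci = f"{_fmt(est.ci_low, nd)} to {_fmt(est.ci_high, nd)}"
        value = _fmt(est.value, nd)
        if f.name in _PROPORTIONS and est.value is not None and math.isfinite(est.value):
            value += f" ({est.value:.0%})"
        note = f" — {est.note}" if est.note else ""
        lines.append(f"| {f.name} | {value}{note} | {ci} |")
    return "\n".join(lines) + "\n"
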