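"""The confusion-matrix metric ledger, interval methods, and their identities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mews_eval as me

# The alive-positive matrix of the reference evaluation: 183/73/3/4.
REFERENCE_MATRIX = me.ConfusionMatrix(183, 73, 3, 4, "alive", "deceased")


@pytest.fixture(scope="module")
def ref_report():
    return me.metric_report(REFERENCE_MATRIX)


@pytest.mark.parametrize(
    "name,decimals,expected",
    [
        ("prevalence_positive", 3, 0.707),
        ("prevalence_negative", 3, 0.293),
        ("accuracy", 3, 0.711),
        ("misclassification_rate", 3, 0.289),
        ("sensitivity", 3, 0.984),
        ("specificity", 3, 0.052),
        ("ppv", 3, 0.715),
        ("npv", 3, 0.571),
        ("lr_positive", 3, 1.038),
        ("lr_negative", 3, 0.310),
        ("odds_ratio", 2, 3.34),
        ("relative_risk", 2, 1.67),
        ("difference_in_proportions", 3, 0.286),
        ("arr", 3, -0.286),
        ("rrr", 3, -0.668),
        ("youden_j", 3, 0.036),
        ("nnt", 2, 3.49),
        ("nnd", 1, 27.9),
        ("nnm", 2, 3.46),
        ("kappa", 3, 0.049),
    ],
)
def test_reference_ledger_point_estimates(ref_report, name, decimals, expected):
    """Every ledger metric reproduces its published value at the printed
    number of decimals, all from the single 183/73/3/4 matrix."""
    assert round(getattr(ref_report, name).value, decimals) == pytest.approx(expected)


def test_reference_margins(ref_report):
    m = ref_report.matrix
    assert (m.r1, m.r2, m.c1, m.c2, m.t) == (256, 7, 186, 77, 263)


def test_error_odds_ratio_is_the_formula_not_the_misprint(ref_report):
    """The sensitivity/specificity odds formula evaluates to (183/3)/(4/73);
    the ledger reports that value exactly."""
    assert ref_report.error_odds_ratio.value == pytest.approx((183 / 3) / (4 / 73))


def test_nnt_interval_unbounded_when_dp_interval_crosses_zero(ref_report):
    assert math.isinf(ref_report.nnt.ci_high)
    assert ref_report.nnt.ci_low > 0
    assert math.isinf(ref_report.nnd.ci_high)


def test_perfect_classifier():
    rep = me.metric_report(me.ConfusionMatrix(50, 0, 0, 50))
    for name in ("sensitivity", "specificity", "accuracy", "kappa", "youden_j"):
        assert getattr(rep, name).value == pytest.approx(1.0)
    assert rep.misclassification_rate.value == 0.0
    assert math.isinf(rep.nnm.value)


matrices = st.tuples(
    st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
).filter(lambda cells: sum(cells) > 0)


@given(matrices)
def test_accuracy_plus_misclassification_is_one(cells):
    rep = me.metric_report(me.ConfusionMatrix(*cells))
    assert rep.accuracy.value + rep.misclassification_rate.value == pytest.approx(1.0)


@given(matrices.filter(lambda cells: all(c > 0 for c in cells)))
def test_dor_equals_cross_product_odds_ratio(cells):
    """DOR computed from sensitivity/specificity equals ad/bc algebraically."""
    rep = me.metric_report(me.ConfusionMatrix(*cells))
    assert rep.diagnostic_odds_ratio.value == pytest.approx(rep.odds_ratio.value)


@given(matrices.filter(lambda cells: all(c > 0 for c in cells)))
def test_orientation_swap_identities(cells):
    """Relabelling the positive class maps sens<->spec and ppv<->npv, maps
    LR+ to 1/LR-, and leaves the cross-product odds ratio unchanged."""
    m = me.ConfusionMatrix(*cells)
    r1, r2 = me.metric_report(m), me.metric_report(m.swap_orientation())
    assert r2.sensitivity.value == pytest.approx(r1.specificity.value)
    assert r2.specificity.value == pytest.approx(r1.sensitivity.value)
    assert r2.ppv.value == pytest.approx(r1.npv.value)
    assert r2.npv.value == pytest.approx(r1.ppv.value)
    assert r2.lr_positive.value == pytest.approx(1 / r1.lr_negative.value)
    assert r2.odds_ratio.value == pytest.approx(r1.odds_ratio.value)


@given(matrices.filter(lambda cells: sum(cells) >= 2))
def test_kappa_invariant_under_transposition(cells):
    m = me.ConfusionMatrix(*cells)
    k1, _ = me.cohen_kappa(m)
    k2, _ = me.cohen_kappa(m.transpose())
    assert k1 == pytest.approx(k2, nan_ok=True)


def test_kappa_reference_exact_rationals():
    p_o = 187 / 263
    p_e = 48155 / 69169
    k, _ = me.cohen_kappa(REFERENCE_MATRIX)
    assert k == pytest.approx((p_o - p_e) / (1 - p_e))
    assert round(k, 3) == 0.049


def test_kappa_perfect_and_independent():
    assert me.cohen_kappa(me.ConfusionMatrix(10, 0, 0, 10))[0] == pytest.approx(1.0)
    # cells proportional to margin products: observed = chance agreement
    assert me.cohen_kappa(me.ConfusionMatrix(2, 4, 3, 6))[0] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# interval methods


def test_wilson_zero_numerator_lower_bound_is_zero():
    lo, hi = me.proportion_ci(0, 10)
    assert lo == 0.0
    assert 0 < hi < 1


def test_wilson_reference_mortality_interval():
    """77/263 mortality: the interval matches the published 24.1%-35.0% at
    two decimals."""
    lo, hi = me.proportion_ci(77, 263)
    assert round(lo, 2) == 0.24
    assert round(hi, 2) == 0.35
    assert lo < 77 / 263 < hi


def test_wilson_agrees_with_reference_implementation():
    smp = pytest.importorskip("statsmodels.stats.proportion")
    for k, n in [(0, 10), (3, 10), (77, 263), (500, 1000)]:
        lo, hi = me.proportion_ci(k, n)
        elo, ehi = smp.proportion_confint(k, n, alpha=0.05, method="wilson")
        assert lo == pytest.approx(elo, abs=1e-10)
        assert hi == pytest.approx(ehi, abs=1e-10)


def test_wilson_coverage_simulation():
    """Monte-Carlo coverage at n=263, p=0.3 stays within 2% of nominal 95%."""
    rng = np.random.default_rng(7)
    n, p, reps = 263, 0.3, 10_000
    ks = rng.binomial(n, p, size=reps)
    covered = 0
    cache: dict[int, tuple[float, float]] = {}
    for k in ks:
        if k not in cache:
            cache[int(k)] = me.proportion_ci(int(k), n)
        lo, hi = cache[int(k)]
        covered += lo <= p <= hi
    assert covered / reps >= 0.93


def test_ratio_ci_brackets_reference_or():
    lo, hi, corrected = me.ratio_ci(REFERENCE_MATRIX, "odds_ratio")
    assert not corrected
    assert lo < 3.34 < hi
    assert hi / lo > 5  # small cells: wide interval


def test_ratio_ci_symmetric_matrix():
    lo, hi, _ = me.ratio_ci(me.ConfusionMatrix(5, 5, 5, 5), "odds_ratio")
    assert math.log(lo) == pytest.approx(-math.log(hi))


def test_ratio_ci_zero_cell_corrected():
    lo, hi, corrected = me.ratio_ci(me.ConfusionMatrix(10, 0, 5, 5), "odds_ratio")
    assert corrected
    assert 0 < lo < hi < math.inf


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        me.metric_report(me.ConfusionMatrix(0, 0, 0, 0))


def test_zero_margin_flags_affected_metrics_only():
    rep = me.metric_report(me.ConfusionMatrix(5, 3, 0, 0))  # r2 = 0
    assert math.isnan(rep.npv.value) and rep.npv.note
    assert rep.accuracy.value == pytest.approx(5 / 8)


def test_markdown_report_mentions_infinite_bounds(ref_report):
    md = me.metrics.report_markdown(ref_report)
    assert "to infinite" in md  # NNT/NND upper bounds
    assert "183 (a or TP)" in md
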