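"""Threshold classification, cut-point selection and dichotomized models."""

import numpy as np
import pytest

import mews_eval as me


def test_reference_classification_at_3(ref_cohort):
    m = me.classification_at_threshold(ref_cohort, 3)
    assert (m.a, m.d, m.b, m.c) == (44, 113, 73, 33)
    assert m.positive_label == "deceased"


def test_reference_classification_at_0_everyone_positive(ref_cohort):
    m = me.classification_at_threshold(ref_cohort, 0)
    assert (m.a, m.b, m.d, m.c) == (77, 186, 0, 0)


def test_classification_matches_per_record_enumeration(toy_cohort):
    for t in range(7):
        m = me.classification_at_threshold(toy_cohort, t)
        cells = {"a": 0, "b": 0, "c": 0, "d": 0}
        for rec in toy_cohort.records:
            pred = rec.score >= t
            key = {(True, 1): "a", (True, 0): "b", (False, 1): "c", (False, 0): "d"}[
                (pred, rec.outcome)
            ]
            cells[key] += 1
        assert (m.a, m.b, m.c, m.d) == tuple(cells.values())
        assert m.t == toy_cohort.n


def test_cells_sum_to_n_and_margins(ref_cohort):
    for t in range(9):
        m = me.classification_at_threshold(ref_cohort, t)
        assert m.t == 263
        assert m.c1 == 77 and m.c2 == 186


def test_scan_reference_row(ref_cohort):
    rows = {r.threshold: r for r in me.threshold_scan(ref_cohort)}
    assert round(rows[2].sensitivity_pct, 1) == 81.8
    assert round(rows[2].one_minus_specificity_pct, 1) == 64.5
    assert rows[2].tp == 63 and rows[2].fp == 120


def test_scan_bottom_row_is_degenerate(ref_cohort):
    rows = me.threshold_scan(ref_cohort)
    bottom = rows[-1]
    assert bottom.threshold == 0
    assert bottom.sensitivity_pct == 100.0
    assert bottom.one_minus_specificity_pct == 100.0
    assert bottom.youden_diff_pct == pytest.approx(0.0)


def test_scan_perfectly_separated_toy():
    cohort = me.Cohort.from_arrays([5, 0], [1, 0])
    rows = {r.threshold: r for r in me.threshold_scan(cohort)}
    assert rows[5].sensitivity_pct == 100.0
    assert rows[5].one_minus_specificity_pct == 0.0


def test_scan_consistent_with_classification(ref_cohort):
    for row in me.threshold_scan(ref_cohort):
        m = me.classification_at_threshold(ref_cohort, row.threshold)
        assert row.sensitivity_pct == pytest.approx(100 * m.a / m.c1)
        assert row.one_minus_specificity_pct == pytest.approx(100 * m.b / m.c2)
        assert (row.tp, row.tn, row.fp, row.fn) == (m.a, m.d, m.b, m.c)


def test_select_cutpoint_reference(ref_cohort):
    cut, diff = me.select_cutpoint(me.threshold_scan(ref_cohort))
    assert cut == 3
    assert round(diff, 1) == pytest.approx(17.9)  # 57.1% - 39.2% at full precision


def test_select_cutpoint_linear_search_oracle():
    rows = me.threshold_scan(me.Cohort.from_arrays([0, 1, 2, 3], [0, 1, 0, 1]))
    best = None
    for r in rows:  # independent argmax with higher-threshold tie-break
        if best is None or r.youden_diff_pct > best.youden_diff_pct or (
            r.youden_diff_pct == best.youden_diff_pct and r.threshold > best.threshold
        ):
            best = r
    assert me.select_cutpoint(rows) == (best.threshold, best.youden_diff_pct)


def test_select_cutpoint_tie_prefers_higher_threshold():
    rows = [
        me.ThresholdScanRow(2, 50.0, 10.0, 40.0, 1, 1, 1, 1),
        me.ThresholdScanRow(1, 60.0, 20.0, 40.0, 1, 1, 1, 1),
    ]
    assert me.select_cutpoint(rows)[0] == 2


def test_probability_rule_reference_matrix(ref_cohort, ref_fit):
    """The 0.5 fitted-probability rule predicts death only at the scores whose
    fitted probability exceeds one half, giving 7 predicted deaths."""
    m = me.classification_at_probability(ref_fit, ref_cohort, p_cut=0.5)
    assert m.positive_label == "alive"
    assert (m.a, m.b, m.c, m.d) == (183, 73, 3, 4)
    assert m.r2 == 7


def test_probability_rule_extreme_cut(ref_cohort, ref_fit):
    m = me.classification_at_probability(ref_fit, ref_cohort, p_cut=0.0)
    assert m.a == 0 and m.b == 0
    assert m.c == ref_cohort.n_alive and m.d == ref_cohort.n_deceased


def test_probability_rule_equivalent_to_score_threshold(ref_cohort, ref_fit):
    """With a monotone-increasing fit, cutting fitted probability at p equals
    cutting the score at the smallest s with fitted probability > p."""
    for p_cut in (0.2, 0.3, 0.4, 0.5, 0.55):
        prob_m = me.classification_at_probability(ref_fit, ref_cohort, p_cut=p_cut)
        thresholds = [
            s for s in range(9) if me.predicted_probability(ref_fit, s) > p_cut
        ]
        t = min(thresholds) if thresholds else 9
        score_m = me.classification_at_threshold(ref_cohort, t)
        # same rule, opposite orientation: cells map a<->d, b<->c
        assert (prob_m.a, prob_m.b, prob_m.c, prob_m.d) == (
            score_m.d, score_m.c, score_m.b, score_m.a,
        )


def test_dichotomized_reference(ref_cohort):
    d = me.dichotomized_model(ref_cohort, 3)
    assert round(d.odds_ratio.value, 1) == 2.1
    assert round(d.relative_risk.value, 1) == 1.7
    assert round(d.chi_square, 1) == 7.0
    assert round(d.p_value, 4) == 0.0080
    assert round(d.misclassification.value, 2) == 0.40


def test_dichotomized_misclassification_is_one_minus_accuracy(ref_cohort):
    d = me.dichotomized_model(ref_cohort, 3)
    rep = me.metric_report(d.matrix)
    assert d.misclassification.value == pytest.approx(1 - rep.accuracy.value)


def test_dichotomized_zero_cell_policy():
    """A cut with no deaths below it: RR unbounded, corrected interval flagged."""
    cohort = me.Cohort.from_arrays([0, 0, 1, 3, 3, 4], [0, 0, 0, 1, 0, 1])
    d = me.dichotomized_model(cohort, 3)
    assert np.isinf(d.relative_risk.value)
    assert d.relative_risk.note is not None
    assert np.isfinite(d.relative_risk.ci_low)


def test_dichotomized_requires_both_groups(ref_cohort):
    with pytest.raises(me.errors.DegenerateDataError):
        me.dichotomized_model(ref_cohort, 100)
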