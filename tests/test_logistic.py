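"""The maximum-likelihood logistic fit and its derived statistics."""

import numpy as np
import pytest

import mews_eval as me
from mews_eval.errors import DegenerateDataError, SeparationError
from conftest import random_cohort


# ---------------------------------------------------------------------------
# fitting


def test_symmetric_cohort_fits_to_zero():
    """One death and one survivor at each of two scores: the likelihood is
    maximized at beta0 = beta1 = 0 (logit one-half everywhere)."""
    cohort = me.Cohort.from_arrays([0, 0, 1, 1], [1, 0, 1, 0])
    fit = me.fit_logistic(cohort)
    assert fit.converged
    assert fit.beta0 == pytest.approx(0.0, abs=1e-8)
    assert fit.beta1 == pytest.approx(0.0, abs=1e-8)
    stat, p = me.whole_model_test(fit)
    assert stat == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0)


def test_fit_matches_grid_search_oracle():
    """On a 6-patient cohort the Newton fit agrees with direct grid-search
    maximization of the Bernoulli log-likelihood."""
    cohort = me.Cohort.from_arrays([0, 0, 1, 2, 2, 3], [0, 1, 0, 1, 0, 1])
    scores = cohort.scores.astype(float)
    y = cohort.outcomes.astype(float)

    def loglik(b0, b1):
        eta = b0 + b1 * scores
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    # three-stage grid refinement, independent of the Newton path
    centre, width = (0.0, 0.0), 4.0
    for _ in range(6):
        b0s = np.linspace(centre[0] - width, centre[0] + width, 41)
        b1s = np.linspace(centre[1] - width, centre[1] + width, 41)
        ll = np.array([[loglik(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        centre, width = (b0s[i], b1s[j]), width / 8

    fit = me.fit_logistic(cohort)
    assert fit.beta0 == pytest.approx(centre[0], abs=1e-4)
    assert fit.beta1 == pytest.approx(centre[1], abs=1e-4)
    assert fit.loglik_full >= loglik(*centre) - 1e-10


def test_agrees_with_statsmodels_on_random_cohorts():
    """Cross-check against an independent logistic implementation."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(20)
    for _ in range(20):
        cohort = random_cohort(rng, n=int(rng.integers(20, 200)))
        try:
            fit = me.fit_logistic(cohort)
        except SeparationError:
            continue
        X = sm.add_constant(cohort.scores.astype(float))
        res = sm.Logit(cohort.outcomes.astype(float), X).fit(disp=0, tol=1e-12)
        assert fit.beta0 == pytest.approx(res.params[0], abs=1e-6)
        assert fit.beta1 == pytest.approx(res.params[1], abs=1e-6)
        assert fit.loglik_full == pytest.approx(res.llf, abs=1e-8)


def test_score_equation_property(ref_cohort, ref_fit):
    """ML logistic fits reproduce the observed event total: sum of fitted
    probabilities equals the number of deaths."""
    fitted = sum(
        me.predicted_probability(ref_fit, int(s)) for s in ref_cohort.scores
    )
    assert fitted == pytest.approx(ref_cohort.n_deceased, abs=1e-6)


def test_lr_statistic_invariances(ref_cohort, ref_fit):
    """Shifting every score by a constant or permuting records leaves the
    whole-model statistic unchanged."""
    stat, _ = me.whole_model_test(ref_fit)
    shifted = me.Cohort.from_arrays(ref_cohort.scores + 5, ref_cohort.outcomes)
    stat_shift, _ = me.whole_model_test(me.fit_logistic(shifted))
    assert stat_shift == pytest.approx(stat, abs=1e-8)

    rng = np.random.default_rng(0)
    perm = rng.permutation(ref_cohort.n)
    permuted = me.Cohort.from_arrays(
        ref_cohort.scores[perm], ref_cohort.outcomes[perm]
    )
    stat_perm, _ = me.whole_model_test(me.fit_logistic(permuted))
    assert stat_perm == pytest.approx(stat, abs=1e-8)


def test_separation_raises():
    cohort = me.Cohort.from_arrays([0, 1, 5, 6], [0, 0, 1, 1])
    with pytest.raises(SeparationError):
        me.fit_logistic(cohort)


def test_single_class_raises():
    cohort = me.Cohort.from_arrays([0, 1, 2], [0, 0, 0])
    with pytest.raises(DegenerateDataError):
        me.fit_logistic(cohort)


# ---------------------------------------------------------------------------
# derived statistics


def test_whole_model_statistic_reference(ref_fit):
    stat, p = me.whole_model_test(ref_fit)
    assert round(stat, 1) == 6.5
    assert round(p, 4) == 0.0107


def test_odds_ratio_reference(ref_fit):
    or_pt, (lo, hi) = me.odds_ratio_per_unit(ref_fit)
    assert round(or_pt, 1) == 1.2
    assert lo < or_pt < hi


def test_predicted_probability_reference(ref_fit):
    assert round(100 * me.predicted_probability(ref_fit, 3), 1) == 30.8
    assert round(100 * me.predicted_probability(ref_fit, 0), 1) == 18.8


def test_predicted_probability_flat_fit():
    fit = me.LogisticFit(0.0, 0.0, -1.0, -1.0, np.eye(2), True, 1)
    for s in (0, 3, 8):
        assert me.predicted_probability(fit, s) == pytest.approx(0.5)


def brute_force_c_index(cohort: me.Cohort) -> float:
    dead = cohort.scores[cohort.outcomes == 1]
    alive = cohort.scores[cohort.outcomes == 0]
    total = conc = ties = 0
    for d in dead:
        for a in alive:
            total += 1
            if d > a:
                conc += 1
            elif d == a:
                ties += 1
    return (conc + 0.5 * ties) / total


def test_c_index_reference_exact_fraction(ref_cohort):
    c, (lo, hi) = me.concordance_index(ref_cohort)
    assert c == pytest.approx(8629 / 14322)
    assert round(c, 2) == 0.60
    assert c == pytest.approx(brute_force_c_index(ref_cohort))
    assert lo < c < hi


def test_c_index_extremes():
    separated = me.Cohort.from_arrays([0, 1, 5, 6], [0, 0, 1, 1])
    assert me.concordance_index(separated)[0] == 1.0
    tied = me.Cohort.from_arrays([2, 2, 2, 2], [0, 1, 0, 1])
    assert me.concordance_index(tied)[0] == 0.5


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_c_index_matches_pair_enumeration(seed):
    """Count arithmetic equals O(n^2) pair enumeration on random cohorts."""
    rng = np.random.default_rng(seed)
    cohort = random_cohort(rng, n=int(rng.integers(10, 500)))
    c, _ = me.concordance_index(cohort)
    assert c == pytest.approx(brute_force_c_index(cohort), abs=1e-12)


def test_c_index_single_class_raises():
    with pytest.raises(DegenerateDataError):
        me.concordance_index(me.Cohort.from_arrays([1, 2], [1, 1]))


def test_model_summary_fitted_probabilities_monotone(ref_fit, ref_cohort):
    summary = me.model_summary(ref_fit, ref_cohort)
    probs = [summary.fitted_probability[s] for s in sorted(summary.fitted_probability)]
    assert all(a < b for a, b in zip(probs, probs[1:]))
    assert set(summary.fitted_probability) == set(range(9))
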