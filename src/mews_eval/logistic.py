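"""Univariable logistic prognostic model of mortality on MEWS.

The model is logit Pr(death | score s) = beta0 + beta1 * s, fitted by
maximum likelihood with Newton-Raphson on the two-parameter concave
log-likelihood.  Because the predictor is a small set of integer scores,
fitting operates on aggregated (score, deaths, total) triples rather than
patient rows; the likelihood is identical.

Reported alongside the coefficients:

* the whole-model likelihood-ratio statistic 2*(l_full - l_null), chi-square
  with 1 df against the intercept-only model;
* the per-unit odds ratio exp(beta1) with a Wald interval on the log scale;
* the concordance index (C-statistic) of the raw score: the probability a
  randomly chosen deceased patient outscores a randomly chosen survivor,
  ties credited one half — computed by count arithmetic over the per-score
  tallies, with a Hanley-McNeil standard error for its interval;
* fitted mortality probabilities at each observed score.

Complete separation (likelihood unbounded, ML estimate nonexistent) raises
``SeparationError`` rather than returning a silently diverged fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, norm

from .cohort import Cohort
from .errors import DegenerateDataError, NotConvergedError, SeparationError

__all__ = [
    "LogisticFit",
    "ModelSummary",
    "fit_logistic",
    "fit_logistic_counts",
    "whole_model_test",
    "predicted_probability",
    "odds_ratio_per_unit",
    "concordance_index",
    "model_summary",
]

_DEFAULT_TOL = 1e-10
_DEFAULT_MAX_ITER = 100


@dataclass(frozen=True)
class LogisticFit:
    beta0: float
    beta1: float
    loglik_full: float
    loglik_null: float
    cov: np.ndarray  # 2x2 inverse observed information
    converged: bool
    n_iter: int

    @property
    def se_beta1(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))


@dataclass(frozen=True)
class ModelSummary:
    chi_square: float
    p_value: float
    odds_ratio_per_unit: float
    or_ci: tuple[float, float]
    c_index: float
    c_index_ci: tuple[float, float]
    fitted_probability: dict[int, float]  # per observed score

    def to_json(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "odds_ratio_per_unit": self.odds_ratio_per_unit,
            "or_ci": list(self.or_ci),
            "c_index": self.c_index,
            "c_index_ci": list(self.c_index_ci),
            "fitted_probability": {str(s): p for s, p in self.fitted_probability.items()},
        }


def _aggregate(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique scores with per-score death counts and totals."""
    scores = cohort.scores
    outcomes = cohort.outcomes
    uniq, inv = np.unique(scores, return_inverse=True)
    deaths = np.bincount(inv, weights=outcomes.astype(float))
    totals = np.bincount(inv).astype(float)
    return uniq.astype(float), deaths, totals


def fit_logistic_counts(
    scores: np.ndarray,
    deaths: np.ndarray,
    totals: np.ndarray,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _DEFAULT_MAX_ITER,
) -> LogisticFit:
    """Newton-Raphson ML fit on aggregated (score, deaths, total) data.

    The per-patient Bernoulli likelihood and this binomial aggregation have
    identical score and information functions, so the fit is the same.
    """
    scores = np.asarray(scores, dtype=float)
    deaths = np.asarray(deaths, dtype=float)
    totals = np.asarray(totals, dtype=float)
    d_tot = deaths.sum()
    n_tot = totals.sum()
    if d_tot == 0 or d_tot == n_tot:
        raise DegenerateDataError("only one outcome class present")
    if np.count_nonzero(totals > 0) < 2 or len(np.unique(scores[totals > 0])) < 2:
        raise DegenerateDataError("need at least two distinct scores")

    # Complete separation: every death above every survival (or vice versa)
    # makes the likelihood unbounded in beta1.
    with_death = scores[deaths > 0]
    with_surv = scores[(totals - deaths) > 0]
    if with_death.min() > with_surv.max() or with_death.max() < with_surv.min():
        raise SeparationError(
            "outcome classes are completely separated by score; "
            "the ML estimate does not exist"
        )

    p_bar = d_tot / n_tot
    loglik_null = d_tot * np.log(p_bar) + (n_tot - d_tot) * np.log1p(-p_bar)

    X = np.column_stack([np.ones_like(scores), scores])
    beta = np.array([np.log(p_bar / (1 - p_bar)), 0.0])

    def loglik(b: np.ndarray) -> float:
        eta = X @ b
        # sum over aggregated cells: d*eta - n*log(1+e^eta)
        return float(deaths @ eta - totals @ np.logaddexp(0.0, eta))

    ll = loglik(beta)
    converged = False
    n_iter = 0
    info = None
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = totals * mu * (1 - mu)
        grad = X.T @ (deaths - totals * mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise SeparationError("singular information matrix during fit") from None
        # step-halving keeps the ascent monotone on extreme starts
        new_beta = beta + step
        new_ll = loglik(new_beta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = loglik(new_beta)
            halvings += 1
        beta, delta, ll = new_beta, new_ll - ll, new_ll
        if abs(beta[1]) > 30:
            raise SeparationError("coefficient diverging; quasi-separated data")
        if abs(delta) < tol:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    w = totals * mu * (1 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return LogisticFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        loglik_full=ll,
        loglik_null=float(loglik_null),
        cov=cov,
        converged=converged,
        n_iter=n_iter,
    )


def fit_logistic(
    cohort: Cohort,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _DEFAULT_MAX_ITER,
) -> LogisticFit:
    """ML fit of logit Pr(death) = beta0 + beta1*score on a cohort."""
    if cohort.n == 0:
        raise DegenerateDataError("empty cohort")
    return fit_logistic_counts(*_aggregate(cohort), tol=tol, max_iter=max_iter)


def whole_model_test(fit: LogisticFit) -> tuple[float, float]:
    """Likelihood-ratio chi-square (1 df) against the intercept-only model."""
    if not fit.converged:
        raise NotConvergedError("whole-model test requires a converged fit")
    stat = max(0.0, 2.0 * (fit.loglik_full - fit.loglik_null))
    return stat, float(chi2.sf(stat, df=1))


def predicted_probability(fit: LogisticFit, score: float) -> float:
    """Fitted mortality probability 1/(1+exp(-(beta0+beta1*score)))."""
    if not fit.converged:
        raise NotConvergedError("prediction requires a converged fit")
    return float(expit(fit.beta0 + fit.beta1 * score))


def odds_ratio_per_unit(
    fit: LogisticFit, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """exp(beta1) with a Wald interval on the log-odds scale."""
    if not fit.converged:
        raise NotConvergedError("odds ratio requires a converged fit")
    z = norm.ppf(0.5 + level / 2)
    se = fit.se_beta1
    return float(np.exp(fit.beta1)), (
        float(np.exp(fit.beta1 - z * se)),
        float(np.exp(fit.beta1 + z * se)),
    )


def concordance_index(
    cohort: Cohort, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """C-statistic of the raw score for deceased vs alive, ties credited 1/2.

    Count arithmetic over per-score tallies: for each score s, the deaths at
    s are concordant with all survivors scoring strictly below s and tied
    with survivors at s.  Interval: Hanley-McNeil standard error.
    """
    scores, deaths, totals = _aggregate(cohort)
    survivors = totals - deaths
    n_d = deaths.sum()
    n_a = survivors.sum()
    if n_d == 0 or n_a == 0:
        raise DegenerateDataError("both outcome classes required for the C-index")
    surv_below = np.concatenate([[0.0], np.cumsum(survivors)[:-1]])
    concordant = float(deaths @ surv_below)
    tied = float(deaths @ survivors)
    pairs = n_d * n_a
    c = (concordant + 0.5 * tied) / pairs

    q1 = c / (2 - c)
    q2 = 2 * c * c / (1 + c)
    var = (c * (1 - c) + (n_d - 1) * (q1 - c * c) + (n_a - 1) * (q2 - c * c)) / pairs
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(0.5 + level / 2)
    return float(c), (max(0.0, c - z * se), min(1.0, c + z * se))


def model_summary(
    fit: LogisticFit, cohort: Cohort, level: float = 0.95
) -> ModelSummary:
    """Assemble the reporting summary: LR test, per-unit OR, C-index, and
    fitted probabilities at every observed score."""
    stat, p = whole_model_test(fit)
    or_pt, or_ci = odds_ratio_per_unit(fit, level=level)
    c, c_ci = concordance_index(cohort, level=level)
    fitted = {
        int(s): predicted_probability(fit, int(s))
        for s in sorted(np.unique(cohort.scores))
    }
    return ModelSummary(
        chi_square=stat,
        p_value=p,
        odds_ratio_per_unit=or_pt,
        or_ci=or_ci,
        c_index=c,
        c_index_ci=c_ci,
        fitted_probability=fitted,
    )
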