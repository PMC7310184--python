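"""Nonparametric bootstrap internal validation of the whole-model statistic.

Each cycle resamples the n patient records with replacement
(unstratified case resampling), refits the univariable logistic model,
and records its likelihood-ratio chi-square; the 95% percentile interval
of the resampled statistics is the reported range of probable population
values.  Resamples where the fit is impossible (a single outcome class)
or where the ML estimate does not exist (complete separation) are counted
and excluded, never replaced by zeros.

All randomness flows from the caller's seed through one generator owned
by the call; nothing touches global random state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .errors import DegenerateDataError, SeparationError
from .logistic import fit_logistic_counts

__all__ = ["BootstrapResult", "bootstrap_whole_model"]


@dataclass(frozen=True)
class BootstrapResult:
    n_resamples: int
    statistic_per_resample: tuple[float, ...]  # successful cycles only
    percentile_interval: tuple[float, float]
    seed: int
    n_failed: int

    def to_json(self, include_statistics: bool = False) -> dict:
        out = {
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "n_failed": self.n_failed,
            "percentile_interval": list(self.percentile_interval),
        }
        if include_statistics:
            out["statistic_per_resample"] = list(self.statistic_per_resample)
        return out


def bootstrap_whole_model(
    cohort: Cohort,
    n_resamples: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap of the whole-model LR chi-square.

    Warns (``RuntimeWarning``) when more than 10% of resamples fail; raises
    ``DegenerateDataError`` when none succeed.  Identical (cohort,
    n_resamples, seed) gives identical output.
    """
    if seed is None:
        raise ValueError("a seed is required; no implicit global randomness")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    scores = cohort.scores
    outcomes = cohort.outcomes
    n = cohort.n
    if n == 0:
        raise DegenerateDataError("empty cohort")
    rng = np.random.default_rng(seed)

    # aggregate each resample over the distinct (score, outcome) cells; the
    # refit then runs on at most (#unique scores) rows
    uniq, inv = np.unique(scores, return_inverse=True)
    stats: list[float] = []
    n_failed = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        cell_deaths = np.bincount(inv[idx], weights=outcomes[idx].astype(float),
                                  minlength=len(uniq))
        cell_totals = np.bincount(inv[idx], minlength=len(uniq)).astype(float)
        keep = cell_totals > 0
        try:
            fit = fit_logistic_counts(uniq[keep], cell_deaths[keep], cell_totals[keep])
        except (DegenerateDataError, SeparationError):
            n_failed += 1
            continue
        stats.append(max(0.0, 2.0 * (fit.loglik_full - fit.loglik_null)))
    if not stats:
        raise DegenerateDataError("no bootstrap resample could be fitted")
    if n_failed > 0.10 * n_resamples:
        warnings.warn(
            f"{n_failed}/{n_resamples} bootstrap resamples failed to fit",
            RuntimeWarning,
            stacklevel=2,
        )
    arr = np.sort(np.array(stats))
    alpha = 1 - level
    lo, hi = np.quantile(arr, [alpha / 2, 1 - alpha / 2])
    return BootstrapResult(
        n_resamples=n_resamples,
        statistic_per_resample=tuple(float(s) for s in stats),
        percentile_interval=(float(lo), float(hi)),
        seed=int(seed),
        n_failed=n_failed,
    )
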