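"""Synthetic cohort generation with the structure the analysis assumes.

A cohort is defined by a categorical distribution over integer scores
0..S_max and a logistic mortality link: scores are drawn i.i.d. from the
distribution and each outcome is Bernoulli with
Pr(death | s) = 1/(1 + exp(-(beta0 + beta1*s))).  This is exactly the
data-generating frame under which the prognostic model is correctly
specified, so parameter recovery is a meaningful end-to-end check of the
fitting code.

``reference_spec`` returns the spec whose score frequencies equal the
reconstructed reference cohort's (mass on scores 0-8) and whose link
parameters are that cohort's ML estimates — a realistic template for
simulation studies at the escalation-of-care scale (n=263, ~29% mortality).

``generate_vitals_cohort`` additionally synthesizes, for every drawn
score, one raw-vitals row that scores exactly to it under a given scoring
table, exercising the scoring pipeline end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .cohort import Cohort
from .datasets import reference_cohort
from .errors import UnachievableScoreError
from .logistic import fit_logistic
from .scoring import AVPU_LEVELS, ScoringTable, VitalSigns, score_mews

__all__ = ["CohortSpec", "generate_cohort", "reference_spec", "generate_vitals_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    n: int
    score_distribution: tuple[float, ...]  # index = score
    beta0: float
    beta1: float
    seed: int

    def __post_init__(self) -> None:
        p = np.asarray(self.score_distribution, dtype=float)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(p) == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("score_distribution must be non-negative and sum to 1")

    def to_json(self) -> dict:
        return {
            "n": self.n,
            "score_distribution": list(self.score_distribution),
            "beta0": self.beta0,
            "beta1": self.beta1,
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        with Path(path).open(encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            n=int(doc["n"]),
            score_distribution=tuple(float(x) for x in doc["score_distribution"]),
            beta0=float(doc["beta0"]),
            beta1=float(doc["beta1"]),
            seed=int(doc["seed"]),
        )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw scores i.i.d. from the spec's distribution and outcomes from the
    logistic link; deterministic under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    p = np.asarray(spec.score_distribution, dtype=float)
    scores = rng.choice(len(p), size=spec.n, p=p / p.sum())
    probs = expit(spec.beta0 + spec.beta1 * scores)
    outcomes = (rng.random(spec.n) < probs).astype(int)
    width = max(4, len(str(spec.n)))
    ids = [f"S{i + 1:0{width}d}" for i in range(spec.n)]
    return Cohort.from_arrays(scores, outcomes, ids)


def reference_spec(n: int = 263, seed: int = 0) -> CohortSpec:
    """Spec mirroring the reconstructed reference cohort: its empirical score
    frequencies (scores 0-8) and its ML logistic-link estimates."""
    cohort = reference_cohort()
    counts = np.bincount(cohort.scores)
    fit = fit_logistic(cohort)
    return CohortSpec(
        n=n,
        score_distribution=tuple(counts / counts.sum()),
        beta0=fit.beta0,
        beta1=fit.beta1,
        seed=seed,
    )


def _component_value_for_points(
    table: ScoringTable, component: str, points: int
) -> float | str | None:
    """A representative measurement worth exactly ``points``: the midpoint of
    the first band with that score (AVPU: the first level with that score)."""
    if component == "avpu":
        for level in AVPU_LEVELS:
            if table.avpu[level] == points:
                return level
        return None
    for band in table.components[component]:
        if band.points == points:
            return (band.lo + band.hi) / 2.0
    return None


def _decompose_score(table: ScoringTable, target: int) -> dict[str, int]:
    """Split a target total into per-component points, choosing the
    lexicographically smallest achievable points vector over components in
    sorted-name order (AVPU last).  Deterministic by construction."""
    names = sorted(table.components) + ["avpu"]
    achievable = [
        sorted({b.points for b in table.components[n]}) if n != "avpu"
        else sorted(set(table.avpu.values()))
        for n in names
    ]
    # max total achievable by the remaining components, for feasibility pruning
    suffix_max = [0] * (len(names) + 1)
    for i in range(len(names) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + max(achievable[i])

    assignment: dict[str, int] = {}
    remaining = target
    for i, name in enumerate(names):
        for pts in achievable[i]:
            if pts <= remaining and remaining - pts <= suffix_max[i + 1]:
                assignment[name] = pts
                remaining -= pts
                break
        else:
            raise UnachievableScoreError(
                f"score {target} not achievable under this scoring table"
            )
    if remaining != 0:
        raise UnachievableScoreError(
            f"score {target} not achievable under this scoring table"
        )
    return assignment


def generate_vitals_cohort(
    spec: CohortSpec, table: ScoringTable
) -> tuple[list[dict], Cohort]:
    """Generate a cohort plus one raw-vitals row per patient whose MEWS under
    ``table`` equals the patient's drawn score exactly.

    Returns (vitals rows as dicts with patient_id/vitals/avpu/outcome, cohort).
    Raises ``UnachievableScoreError`` naming the first unachievable score.
    """
    cohort = generate_cohort(spec)
    rows: list[dict] = []
    cache: dict[int, dict[str, int]] = {}
    for rec in cohort.records:
        if rec.score not in cache:
            cache[rec.score] = _decompose_score(table, rec.score)
        points = cache[rec.score]
        row: dict = {"patient_id": rec.patient_id}
        for comp, pts in points.items():
            value = _component_value_for_points(table, comp, pts)
            if value is None:  # decomposition only uses achievable points
                raise UnachievableScoreError(
                    f"no band worth {pts} points for component {comp}"
                )
            row["avpu" if comp == "avpu" else comp] = value
        row["outcome"] = rec.outcome
        rows.append(row)
    # construction check: the synthesized vitals must reproduce each score
    for row, rec in zip(rows, cohort.records):
        vit = VitalSigns(
            heart_rate=row["heart_rate"],
            respiratory_rate=row["respiratory_rate"],
            systolic_bp=row["systolic_bp"],
            temperature=row["temperature"],
            consciousness=row["avpu"],
        )
        assert score_mews(vit, table) == rec.score
    return rows, cohort
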