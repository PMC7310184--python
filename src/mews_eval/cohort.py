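"""Cohort containers and interconversion with cumulative threshold tables.

The central object is a per-patient cohort of (MEWS, vital status) records.
Published score evaluations often print, instead of patient-level data, the
cumulative cross-classification of the rule "predict death iff score >= T"
at every threshold T: true/false positives and negatives with deceased as
the positive class.  Because the TP and FP columns are cumulative sums
(from the top score downward) of the per-score death and survivor counts,
the exact per-score outcome distribution — and hence an order-canonical
per-patient cohort — is recoverable by first differencing.  This module
implements both directions, the compressed per-score counts form, and CSV
round-tripping for all three shapes.

Outcome coding is deceased=1 (the modelled event) and alive=0 throughout;
the string aliases "deceased"/"alive" are accepted on read.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CohortParseError, TableConsistencyError

__all__ = [
    "CohortRecord",
    "Cohort",
    "ScoreOutcomeCounts",
    "ThresholdClassificationTable",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_counts_csv",
    "write_counts_csv",
    "read_threshold_table_csv",
    "write_threshold_table_csv",
    "invert_cumulative_table",
    "cumulate_counts",
    "expand_to_cohort",
    "compress_cohort",
]

_OUTCOME_ALIASES = {"0": 0, "1": 1, "alive": 0, "deceased": 1}


@dataclass(frozen=True)
class CohortRecord:
    """One patient: an opaque identifier, an integer MEWS, and vital status
    (deceased=1, alive=0)."""

    patient_id: str
    score: int
    outcome: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")
        if self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0 or 1, got {self.outcome}")


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of patient records."""

    records: tuple[CohortRecord, ...]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_deceased(self) -> int:
        return sum(r.outcome for r in self.records)

    @property
    def n_alive(self) -> int:
        return self.n - self.n_deceased

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.records], dtype=np.int64)

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([r.outcome for r in self.records], dtype=np.int64)

    @classmethod
    def from_arrays(
        cls,
        scores: Iterable[int],
        outcomes: Iterable[int],
        patient_ids: Iterable[str] | None = None,
    ) -> "Cohort":
        scores = list(scores)
        outcomes = list(outcomes)
        if len(scores) != len(outcomes):
            raise ValueError("scores and outcomes differ in length")
        if patient_ids is None:
            width = max(4, len(str(len(scores))))
            patient_ids = [f"P{i + 1:0{width}d}" for i in range(len(scores))]
        else:
            patient_ids = list(patient_ids)
        return cls(
            tuple(
                CohortRecord(pid, int(s), int(y))
                for pid, s, y in zip(patient_ids, scores, outcomes, strict=True)
            )
        )


@dataclass(frozen=True)
class ScoreOutcomeCounts:
    """Compressed cohort: death and survivor counts per integer score 0..s_max.

    Index i of each tuple is the count at score i.
    """

    deaths: tuple[int, ...]
    survivors: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.deaths) != len(self.survivors):
            raise ValueError("deaths and survivors must cover the same score range")
        if len(self.deaths) == 0:
            raise ValueError("empty counts")
        if any(d < 0 for d in self.deaths) or any(s < 0 for s in self.survivors):
            raise ValueError("counts must be non-negative")

    @property
    def s_max(self) -> int:
        return len(self.deaths) - 1

    @property
    def n_deceased(self) -> int:
        return sum(self.deaths)

    @property
    def n_alive(self) -> int:
        return sum(self.survivors)

    @property
    def n(self) -> int:
        return self.n_deceased + self.n_alive

    @classmethod
    def from_mappings(
        cls, deaths: Mapping[int, int], survivors: Mapping[int, int]
    ) -> "ScoreOutcomeCounts":
        s_max = max(list(deaths) + list(survivors), default=0)
        return cls(
            tuple(int(deaths.get(s, 0)) for s in range(s_max + 1)),
            tuple(int(survivors.get(s, 0)) for s in range(s_max + 1)),
        )


@dataclass(frozen=True)
class ThresholdClassificationTable:
    """Cumulative cross-classification of "predict death iff score >= T".

    Rows are keyed by threshold in descending order over a contiguous
    integer range; deceased is the positive class.  Validated on
    construction: constant class margins (tp+fn = total deceased,
    tn+fp = total alive at every threshold), tp and fp non-increasing in T,
    and — when the minimum threshold is 0 — tp = total deceased and tn = 0
    there, since every score is >= 0.
    """

    thresholds: tuple[int, ...]
    tp: tuple[int, ...]
    tn: tuple[int, ...]
    fp: tuple[int, ...]
    fn: tuple[int, ...]

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) == 0:
            raise TableConsistencyError("empty table")
        lens = {len(t), len(self.tp), len(self.tn), len(self.fp), len(self.fn)}
        if len(lens) != 1:
            raise TableConsistencyError("column lengths differ")
        if list(t) != list(range(t[0], t[0] - len(t), -1)):
            raise TableConsistencyError(
                "thresholds must be a contiguous descending integer range"
            )
        if any(
            v < 0 for col in (self.tp, self.tn, self.fp, self.fn) for v in col
        ):
            raise TableConsistencyError("negative count")
        deceased = {tp + fn for tp, fn in zip(self.tp, self.fn)}
        alive = {tn + fp for tn, fp in zip(self.tn, self.fp)}
        if len(deceased) != 1 or len(alive) != 1:
            raise TableConsistencyError(
                "class margins must be constant across thresholds "
                f"(got deceased totals {sorted(deceased)}, alive totals {sorted(alive)})"
            )
        # tp/fp cumulate from the top score down: non-increasing as T rises
        # == non-decreasing in stored (descending-T) order.
        if any(a > b for a, b in zip(self.tp, self.tp[1:])):
            raise TableConsistencyError("tp must be non-increasing in threshold")
        if any(a > b for a, b in zip(self.fp, self.fp[1:])):
            raise TableConsistencyError("fp must be non-increasing in threshold")
        if self.min_threshold == 0:
            if self.tp[-1] != self.total_deceased or self.tn[-1] != 0:
                raise TableConsistencyError(
                    "at threshold 0 every patient is predicted positive: "
                    "tp must equal total deceased and tn must be 0"
                )

    @property
    def max_threshold(self) -> int:
        return self.thresholds[0]

    @property
    def min_threshold(self) -> int:
        return self.thresholds[-1]

    @property
    def total_deceased(self) -> int:
        return self.tp[0] + self.fn[0]

    @property
    def total_alive(self) -> int:
        return self.tn[0] + self.fp[0]

    def row(self, threshold: int) -> tuple[int, int, int, int]:
        """(tp, tn, fp, fn) at a threshold."""
        i = self.thresholds.index(threshold)
        return self.tp[i], self.tn[i], self.fp[i], self.fn[i]


# ---------------------------------------------------------------------------
# CSV I/O


def read_cohort_csv(path: str | Path) -> Cohort:
    """Read a per-patient cohort from CSV columns patient_id,score,outcome.

    ``outcome`` accepts 0/1 or the aliases alive/deceased (case-insensitive).
    Raises :class:`CohortParseError` naming the offending row on bad input.
    """
    path = Path(path)
    records: list[CohortRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = {"patient_id", "score", "outcome"} - set(reader.fieldnames or ())
        if missing:
            raise CohortParseError(
                f"{path}: missing column(s) {sorted(missing)}"
            )
        for i, row in enumerate(reader, start=2):  # header is line 1
            raw_score = (row["score"] or "").strip()
            try:
                score = int(raw_score)
            except ValueError:
                raise CohortParseError(
                    f"{path}: row {i}: non-integer score {raw_score!r}"
                ) from None
            raw_outcome = (row["outcome"] or "").strip().lower()
            if raw_outcome not in _OUTCOME_ALIASES:
                raise CohortParseError(
                    f"{path}: row {i}: outcome {row['outcome']!r} not in "
                    "{0, 1, alive, deceased}"
                )
            try:
                records.append(
                    CohortRecord(row["patient_id"], score, _OUTCOME_ALIASES[raw_outcome])
                )
            except ValueError as exc:
                raise CohortParseError(f"{path}: row {i}: {exc}") from None
    return Cohort(tuple(records))


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "score", "outcome"])
        for r in cohort.records:
            writer.writerow([r.patient_id, r.score, r.outcome])


def read_counts_csv(path: str | Path) -> ScoreOutcomeCounts:
    """Read per-score counts from CSV columns score,deaths,survivors."""
    path = Path(path)
    deaths: dict[int, int] = {}
    survivors: dict[int, int] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = {"score", "deaths", "survivors"} - set(reader.fieldnames or ())
        if missing:
            raise CohortParseError(f"{path}: missing column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                s = int(row["score"])
                deaths[s] = int(row["deaths"])
                survivors[s] = int(row["survivors"])
            except ValueError as exc:
                raise CohortParseError(f"{path}: row {i}: {exc}") from None
    if not deaths:
        raise CohortParseError(f"{path}: no data rows")
    return ScoreOutcomeCounts.from_mappings(deaths, survivors)


def write_counts_csv(counts: ScoreOutcomeCounts, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["score", "deaths", "survivors"])
        for s in range(counts.s_max + 1):
            writer.writerow([s, counts.deaths[s], counts.survivors[s]])


def read_threshold_table_csv(path: str | Path) -> ThresholdClassificationTable:
    """Read a cumulative table from CSV columns threshold,tp,tn,fp,fn.

    Rows may appear in any order; they are sorted by descending threshold.
    """
    path = Path(path)
    rows: list[tuple[int, int, int, int, int]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = {"threshold", "tp", "tn", "fp", "fn"} - set(reader.fieldnames or ())
        if missing:
            raise CohortParseError(f"{path}: missing column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                rows.append(
                    tuple(int(row[k]) for k in ("threshold", "tp", "tn", "fp", "fn"))
                )
            except ValueError as exc:
                raise CohortParseError(f"{path}: row {i}: {exc}") from None
    if not rows:
        raise CohortParseError(f"{path}: no data rows")
    rows.sort(key=lambda r: -r[0])
    cols = list(zip(*rows))
    return ThresholdClassificationTable(
        thresholds=tuple(cols[0]),
        tp=tuple(cols[1]),
        tn=tuple(cols[2]),
        fp=tuple(cols[3]),
        fn=tuple(cols[4]),
    )


def write_threshold_table_csv(
    table: ThresholdClassificationTable, path: str | Path
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "tp", "tn", "fp", "fn"])
        for i, t in enumerate(table.thresholds):
            writer.writerow([t, table.tp[i], table.tn[i], table.fp[i], table.fn[i]])


# ---------------------------------------------------------------------------
# Cumulative table <-> per-score counts <-> cohort


def invert_cumulative_table(table: ThresholdClassificationTable) -> ScoreOutcomeCounts:
    """Recover per-score outcome counts from a cumulative table by differencing.

    deaths[s] = tp[s] - tp[s+1] and survivors[s] = fp[s] - fp[s+1], with the
    cumulative counts above the maximum threshold taken as 0.  When the
    table's minimum threshold T0 is above 0, the outcome mass at scores
    below T0 is not identifiable score-by-score; it is placed at score T0-1
    so that forward re-cumulation over the table's own thresholds reproduces
    the input exactly.
    """
    t0 = table.min_threshold
    s_max = table.max_threshold
    deaths = [0] * (s_max + 1)
    survivors = [0] * (s_max + 1)
    tp = dict(zip(table.thresholds, table.tp))
    fp = dict(zip(table.thresholds, table.fp))
    for s in range(t0, s_max + 1):
        deaths[s] = tp[s] - tp.get(s + 1, 0)
        survivors[s] = fp[s] - fp.get(s + 1, 0)
    rem_d = table.total_deceased - tp[t0]
    rem_s = table.total_alive - fp[t0]
    if t0 > 0:
        deaths[t0 - 1] = rem_d
        survivors[t0 - 1] = rem_s
    elif rem_d or rem_s:  # unreachable given table validation; defensive
        raise TableConsistencyError("margins inconsistent at threshold 0")
    return ScoreOutcomeCounts(tuple(deaths), tuple(survivors))


def cumulate_counts(counts: ScoreOutcomeCounts) -> ThresholdClassificationTable:
    """Build the cumulative table over thresholds s_max..0 from per-score counts:
    tp[T] = sum of deaths at scores >= T, fp[T] likewise for survivors, and
    fn/tn by subtraction from the class margins."""
    d = np.asarray(counts.deaths)
    s = np.asarray(counts.survivors)
    # reverse cumulative sums: index T -> sum over scores >= T
    tp = np.cumsum(d[::-1])[::-1]
    fp = np.cumsum(s[::-1])[::-1]
    total_d, total_a = int(d.sum()), int(s.sum())
    thresholds = tuple(range(counts.s_max, -1, -1))
    return ThresholdClassificationTable(
        thresholds=thresholds,
        tp=tuple(int(tp[t]) for t in thresholds),
        tn=tuple(total_a - int(fp[t]) for t in thresholds),
        fp=tuple(int(fp[t]) for t in thresholds),
        fn=tuple(total_d - int(tp[t]) for t in thresholds),
    )


def expand_to_cohort(counts: ScoreOutcomeCounts) -> Cohort:
    """Expand per-score counts to a per-patient cohort.

    Record order is canonical — ascending score, deceased before alive at
    each score — and patient identifiers are sequential, so two calls give
    byte-identical CSV output.
    """
    scores: list[int] = []
    outcomes: list[int] = []
    for s in range(counts.s_max + 1):
        scores.extend([s] * counts.deaths[s])
        outcomes.extend([1] * counts.deaths[s])
        scores.extend([s] * counts.survivors[s])
        outcomes.extend([0] * counts.survivors[s])
    return Cohort.from_arrays(scores, outcomes)


def compress_cohort(cohort: Cohort) -> ScoreOutcomeCounts:
    """Tally a cohort into per-score death/survivor counts (inverse of
    :func:`expand_to_cohort` up to record identity)."""
    if cohort.n == 0:
        raise ValueError("cannot compress an empty cohort")
    s_max = int(cohort.scores.max())
    deaths = np.bincount(
        cohort.scores[cohort.outcomes == 1], minlength=s_max + 1
    )
    survivors = np.bincount(
        cohort.scores[cohort.outcomes == 0], minlength=s_max + 1
    )
    return ScoreOutcomeCounts(tuple(int(x) for x in deaths), tuple(int(x) for x in survivors))
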