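"""Aggregate MEWS computation from raw bedside vitals.

The Modified Early Warning Score sums banded points (0-3 per component)
over five bedside measurements: heart rate (beats/min), respiratory rate
(breaths/min), systolic blood pressure (mmHg), temperature (deg C), and
AVPU consciousness level (Alert / responds to Voice / responds to Pain /
Unresponsive).  Band edges differ between institutions, so the scoring
table is configuration, not code: a JSON document of half-open [lo, hi)
bands per numeric component plus an explicit four-entry AVPU map.  A
widely used default banding ships with the package; the downstream
prognostic analysis starts from already-computed scores and does not
depend on it.

Temperature is Celsius only — Fahrenheit-scale values fall outside the
covered range and are rejected rather than converted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .cohort import Cohort, CohortRecord
from .errors import CohortParseError, ScoringRangeError

__all__ = [
    "AVPU_LEVELS",
    "VitalSigns",
    "Band",
    "ScoringTable",
    "default_table",
    "score_component",
    "score_mews",
    "read_vitals_csv",
]

AVPU_LEVELS = ("alert", "voice", "pain", "unresponsive")

#: Plausibility bounds enforced on construction of VitalSigns.
_PLAUSIBLE = {
    "heart_rate": (10.0, 300.0),
    "respiratory_rate": (0.0, 80.0),
    "systolic_bp": (20.0, 300.0),
    "temperature": (25.0, 45.0),
}


@dataclass(frozen=True)
class VitalSigns:
    heart_rate: float
    respiratory_rate: float
    systolic_bp: float
    temperature: float
    consciousness: str  # one of AVPU_LEVELS

    def __post_init__(self) -> None:
        for name, (lo, hi) in _PLAUSIBLE.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"{name}={v} outside plausible range [{lo}, {hi}]"
                )
        if self.consciousness not in AVPU_LEVELS:
            raise ValueError(
                f"consciousness must be one of {AVPU_LEVELS}, got {self.consciousness!r}"
            )


@dataclass(frozen=True)
class Band:
    """Half-open interval [lo, hi) worth ``points``."""

    lo: float
    hi: float
    points: int

    def __contains__(self, value: float) -> bool:
        return self.lo <= value < self.hi


@dataclass(frozen=True)
class ScoringTable:
    """Per-component ordered band lists plus an explicit AVPU point map.

    Validated on construction: bands within a component are disjoint and
    jointly cover a contiguous range, points lie in 0..3, and the AVPU map
    has exactly the four standard levels.
    """

    components: dict[str, tuple[Band, ...]]
    avpu: dict[str, int]

    def __post_init__(self) -> None:
        for name, bands in self.components.items():
            if not bands:
                raise ValueError(f"component {name}: no bands")
            ordered = sorted(bands, key=lambda b: b.lo)
            for b in ordered:
                if not (b.lo < b.hi):
                    raise ValueError(f"component {name}: empty band [{b.lo}, {b.hi})")
                if b.points not in (0, 1, 2, 3):
                    raise ValueError(f"component {name}: points must be 0..3")
            for a, b in zip(ordered, ordered[1:]):
                if a.hi != b.lo:
                    raise ValueError(
                        f"component {name}: bands must tile contiguously; "
                        f"gap or overlap at {a.hi} vs {b.lo}"
                    )
            object.__setattr__(
                self, "components", {**self.components, name: tuple(ordered)}
            )
        if set(self.avpu) != set(AVPU_LEVELS):
            raise ValueError(f"avpu map must have exactly the levels {AVPU_LEVELS}")
        if any(p not in (0, 1, 2, 3) for p in self.avpu.values()):
            raise ValueError("avpu points must be 0..3")

    @property
    def max_score(self) -> int:
        """Largest achievable aggregate score under this table."""
        return sum(
            max(b.points for b in bands) for bands in self.components.values()
        ) + max(self.avpu.values())

    def component_names(self) -> tuple[str, ...]:
        return tuple(self.components) + ("avpu",)

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "ScoringTable":
        return cls(
            components={
                name: tuple(Band(float(b["lo"]), float(b["hi"]), int(b["points"])) for b in bands)
                for name, bands in doc["components"].items()
            },
            avpu={k: int(v) for k, v in doc["avpu"].items()},
        )

    def to_dict(self) -> dict:
        return {
            "components": {
                name: [{"lo": b.lo, "hi": b.hi, "points": b.points} for b in bands]
                for name, bands in self.components.items()
            },
            "avpu": dict(self.avpu),
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoringTable":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def default_table() -> ScoringTable:
    """The packaged default MEWS banding (see ``data/mews_bands.json``)."""
    with resources.files("mews_eval").joinpath("data", "mews_bands.json").open(
        encoding="utf-8"
    ) as fh:
        return ScoringTable.from_dict(json.load(fh))


def score_component(
    value: float | str, component: str, table: ScoringTable
) -> int:
    """Points for one component: the unique band containing ``value``, or the
    AVPU map entry when ``component == "avpu"``."""
    if component == "avpu":
        if value not in table.avpu:
            raise ScoringRangeError(
                f"avpu: level {value!r} not in {tuple(table.avpu)}"
            )
        return table.avpu[value]
    if component not in table.components:
        raise ScoringRangeError(f"unknown component {component!r}")
    for band in table.components[component]:
        if float(value) in band:
            return band.points
    covered = (table.components[component][0].lo, table.components[component][-1].hi)
    raise ScoringRangeError(
        f"{component}: value {value} outside covered range [{covered[0]}, {covered[1]})"
    )


def score_mews(vitals: VitalSigns, table: ScoringTable) -> int:
    """Aggregate MEWS: the sum of the five component scores."""
    total = score_component(vitals.consciousness, "avpu", table)
    for name in ("heart_rate", "respiratory_rate", "systolic_bp", "temperature"):
        total += score_component(getattr(vitals, name), name, table)
    return total


def read_vitals_csv(path: str | Path, table: ScoringTable) -> Cohort:
    """Score a vitals CSV into a cohort of MEWS values.

    Columns: patient_id, heart_rate, respiratory_rate, systolic_bp,
    temperature, avpu, and optionally outcome (0/1 or alive/deceased);
    a missing outcome column yields outcome 0 for every record (scores
    only, no prognostic analysis possible downstream).
    """
    path = Path(path)
    required = {
        "patient_id", "heart_rate", "respiratory_rate", "systolic_bp",
        "temperature", "avpu",
    }
    records: list[CohortRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise CohortParseError(f"{path}: missing column(s) {sorted(missing)}")
        has_outcome = "outcome" in (reader.fieldnames or ())
        for i, row in enumerate(reader, start=2):
            try:
                vitals = VitalSigns(
                    heart_rate=float(row["heart_rate"]),
                    respiratory_rate=float(row["respiratory_rate"]),
                    systolic_bp=float(row["systolic_bp"]),
                    temperature=float(row["temperature"]),
                    consciousness=row["avpu"].strip().lower(),
                )
            except ValueError as exc:
                raise CohortParseError(f"{path}: row {i}: {exc}") from None
            outcome = 0
            if has_outcome:
                raw = row["outcome"].strip().lower()
                aliases = {"0": 0, "1": 1, "alive": 0, "deceased": 1}
                if raw not in aliases:
                    raise CohortParseError(
                        f"{path}: row {i}: outcome {row['outcome']!r} invalid"
                    )
                outcome = aliases[raw]
            records.append(
                CohortRecord(row["patient_id"], score_mews(vitals, table), outcome)
            )
    return Cohort(tuple(records))
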