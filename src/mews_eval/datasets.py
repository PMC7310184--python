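"""Packaged reference dataset.

A published single-centre series of 263 consecutive unplanned surgical ICU
admissions (one calendar year) reported the cumulative threshold
cross-classification of bedside MEWS against in-hospital mortality:
true/false positive and negative counts for the rule "predict death iff
MEWS >= T" at every threshold T from 8 down to 0, with deceased as the
positive class.  Those count columns are shipped verbatim as
``data/sicu_escalation_thresholds.csv``; because the TP/FP columns are
cumulative sums of the per-score outcome counts, the exact per-patient
cohort (77 deaths, 186 survivors over scores 0-8) is recoverable by first
differencing — see :mod:`mews_eval.cohort`.
"""

from __future__ import annotations

from importlib import resources

from .cohort import (
    Cohort,
    ScoreOutcomeCounts,
    ThresholdClassificationTable,
    expand_to_cohort,
    invert_cumulative_table,
    read_threshold_table_csv,
)

__all__ = ["load_reference_table", "reference_counts", "reference_cohort"]


def _data_path(name: str):
    return resources.files("mews_eval").joinpath("data", name)


def load_reference_table() -> ThresholdClassificationTable:
    """The published cumulative threshold cross-classification (263 patients)."""
    with resources.as_file(_data_path("sicu_escalation_thresholds.csv")) as p:
        return read_threshold_table_csv(p)


def reference_counts() -> ScoreOutcomeCounts:
    """Per-score death/survivor counts reconstructed from the reference table."""
    return invert_cumulative_table(load_reference_table())


def reference_cohort() -> Cohort:
    """The reconstructed per-patient reference cohort (n=263, 77 deceased)."""
    return expand_to_cohort(reference_counts())
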