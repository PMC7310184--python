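"""Exception hierarchy for the MEWS evaluation toolkit."""


class MewsEvalError(Exception):
    """Base class for all package-specific errors."""


class CohortParseError(MewsEvalError):
    """A cohort/vitals/table file could not be parsed; the message names the offending row."""


class TableConsistencyError(MewsEvalError):
    """A cumulative threshold cross-classification table violates its invariants
    (non-monotone cumulative counts or inconsistent class margins)."""


class DegenerateDataError(MewsEvalError):
    """The data cannot support the requested estimate (e.g. a single outcome
    class, or fewer than two distinct scores for a regression)."""


class SeparationError(MewsEvalError):
    """Complete separation: the logistic likelihood is unbounded and the ML
    estimate does not exist."""


class NotConvergedError(MewsEvalError):
    """An operation required a converged fit but the fit did not converge."""


class ScoringRangeError(MewsEvalError):
    """A vital-sign value falls outside the range covered by the scoring table;
    the message names the component."""


class UnachievableScoreError(MewsEvalError):
    """A target aggregate score cannot be produced under the given scoring table."""


class PipelineError(MewsEvalError):
    """A full-analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
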