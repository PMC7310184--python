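"""Full-analysis driver: chain every stage and write a report bundle.

The bundle mirrors a complete score evaluation: cohort summary with
mortality incidence, logistic model summary, threshold scan with the
selected cut-point starred, the probability-rule confusion matrix with
its full metric ledger (JSON and Markdown), the dichotomized cut-point
model, and the bootstrap validation of the whole-model statistic.  Output
is deterministic for a fixed input and seed; on any stage failure the
partially written files are removed and a ``PipelineError`` naming the
stage is raised.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

from . import bootstrap as _bootstrap
from . import cohort as _cohort
from . import logistic as _logistic
from . import metrics as _metrics
from . import scoring as _scoring
from . import simulate as _simulate
from . import thresholds as _thresholds
from .errors import PipelineError

__all__ = ["RunConfig", "run_full_analysis", "logging_setup"]

log = logging.getLogger("mews_eval")

_INPUT_KINDS = ("cohort", "table", "vitals", "synthetic")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one full analysis run.

    Exactly one input mode applies, named by ``input_kind``: a per-patient
    cohort CSV, a cumulative threshold-table CSV, a raw-vitals CSV scored
    under ``scoring_table_path`` (default banding when omitted), or a
    synthetic-cohort spec JSON.
    """

    input_kind: str
    input_path: str | Path | None
    out_dir: str | Path = "results"
    scoring_table_path: str | Path | None = None
    level: float = 0.95
    cycles: int = 1000
    seed: int = 0
    prob_cut: float = 0.5
    cutpoint_override: int | None = None
    include_bootstrap_statistics: bool = False

    def __post_init__(self) -> None:
        if self.input_kind not in _INPUT_KINDS:
            raise ValueError(f"input_kind must be one of {_INPUT_KINDS}")
        if not (0 < self.level < 1):
            raise ValueError("confidence level must be in (0, 1)")


def logging_setup(verbosity: int = 0) -> None:
    """Structured logs to stderr; patient-level data is never logged at the
    default level.  0 = warnings, 1 = stage progress, 2 = per-threshold rows."""
    level = logging.WARNING if verbosity <= 0 else (
        logging.INFO if verbosity == 1 else logging.DEBUG
    )
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


def _load_cohort(config: RunConfig) -> _cohort.Cohort:
    kind = config.input_kind
    if kind == "cohort":
        return _cohort.read_cohort_csv(config.input_path)
    if kind == "table":
        table = _cohort.read_threshold_table_csv(config.input_path)
        return _cohort.expand_to_cohort(_cohort.invert_cumulative_table(table))
    if kind == "vitals":
        table = (
            _scoring.ScoringTable.from_json(config.scoring_table_path)
            if config.scoring_table_path
            else _scoring.default_table()
        )
        return _scoring.read_vitals_csv(config.input_path, table)
    spec = _simulate.CohortSpec.from_json(config.input_path)
    return _simulate.generate_cohort(spec)


def _write_json(path: Path, payload: dict) -> None:
    with path.open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns {artifact name: path}.  Stage failures remove the partial bundle
    and raise :class:`PipelineError`.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "input"
    try:
        cohort = _load_cohort(config)
        log.info("loaded cohort: n=%d, deceased=%d", cohort.n, cohort.n_deceased)

        stage = "cohort_summary"
        lo, hi = _metrics.proportion_ci(cohort.n_deceased, cohort.n, config.level)
        path = out_dir / "cohort_summary.json"
        _write_json(path, {
            "n": cohort.n,
            "n_deceased": cohort.n_deceased,
            "n_alive": cohort.n_alive,
            "mortality_incidence": cohort.n_deceased / cohort.n,
            "mortality_ci": [lo, hi],
            "confidence_level": config.level,
        })
        written["cohort_summary"] = path

        stage = "model"
        fit = _logistic.fit_logistic(cohort)
        summary = _logistic.model_summary(fit, cohort, level=config.level)
        path = out_dir / "model_summary.json"
        _write_json(path, {
            **summary.to_json(),
            "beta0": fit.beta0,
            "beta1": fit.beta1,
            "loglik_full": fit.loglik_full,
            "loglik_null": fit.loglik_null,
            "n_iter": fit.n_iter,
        })
        written["model_summary"] = path

        stage = "threshold_scan"
        scan = _thresholds.threshold_scan(cohort)
        for row in scan:
            log.debug("threshold %d: sens %.1f%%, 1-spec %.1f%%",
                      row.threshold, row.sensitivity_pct,
                      row.one_minus_specificity_pct)
        cutpoint, diff = _thresholds.select_cutpoint(scan)
        if config.cutpoint_override is not None:
            cutpoint = config.cutpoint_override
        path = out_dir / "threshold_scan.csv"
        _thresholds.write_scan_csv(scan, path, starred_threshold=cutpoint)
        written["threshold_scan"] = path
        log.info("selected cut-point %d (difference %.1f%%)", cutpoint, diff)

        stage = "metric_report"
        matrix = _thresholds.classification_at_probability(
            fit, cohort, p_cut=config.prob_cut
        )
        report = _metrics.metric_report(matrix, level=config.level)
        path = out_dir / "metric_report.json"
        _write_json(path, report.to_json())
        written["metric_report"] = path
        md_path = out_dir / "metric_report.md"
        md_path.write_text(_metrics.report_markdown(report), encoding="utf-8")
        written["metric_report_md"] = md_path

        stage = "dichotomized"
        dichot = _thresholds.dichotomized_model(cohort, cutpoint, level=config.level)
        path = out_dir / "dichotomized.json"
        _write_json(path, dichot.to_json())
        written["dichotomized"] = path

        stage = "bootstrap"
        boot = _bootstrap.bootstrap_whole_model(
            cohort, n_resamples=config.cycles, seed=config.seed, level=config.level
        )
        path = out_dir / "bootstrap.json"
        payload = boot.to_json(include_statistics=config.include_bootstrap_statistics)
        payload["observed_chi_square"] = summary.chi_square
        payload["observed_within_interval"] = bool(
            boot.percentile_interval[0] <= summary.chi_square
            <= boot.percentile_interval[1]
        )
        _write_json(path, payload)
        written["bootstrap"] = path
    except Exception as exc:
        for p in written.values():
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return written
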