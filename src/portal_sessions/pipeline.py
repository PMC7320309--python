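"""End-to-end orchestration: raw exports in, validated metric tables out.

Stages run in fixed order -- ingest, canonical sort, gap analysis /
threshold, sessionization, device inference, classification,
deduplication, metrics, account status -- with record counts logged at
every stage boundary.  The analysis path contains no randomness: identical
inputs and configuration reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import gaps as gaps_mod
from .errors import ConfigError, EstimationError, PortalSessionsError
from .ingest import canonical_sort, read_audit_log
from .metrics import (
    PatientMetrics,
    SessionMetrics,
    cohort_summary,
    dedup_actions,
    patient_metrics,
    patient_metrics_frame,
    session_metrics,
    session_metrics_frame,
)
from .sessions import DEFAULT_MOBILE_MARKERS, Session, assign_sessions
from .status import read_status_log, status_table, summarize_accounts
from .taxonomy import load_taxonomy

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    ``threshold_mode`` is exclusive: ``"fixed"`` uses
    ``threshold_seconds`` as-is; ``"estimate"`` derives the threshold from
    the data as the ``retention`` quantile of non-log-out gaps, falling
    back to ``threshold_seconds`` when estimation is impossible.
    """

    audit_path: Union[str, Path, None] = None
    status_path: Union[str, Path, None] = None
    taxonomy_path: Union[str, Path, None] = None
    out_dir: Union[str, Path, None] = None
    delimiter: str = "\t"
    threshold_mode: str = "fixed"  # "fixed" | "estimate"
    threshold_seconds: float = gaps_mod.DEFAULT_THRESHOLD_SECONDS
    retention: float = gaps_mod.DEFAULT_RETENTION
    mobile_markers: Sequence[str] = DEFAULT_MOBILE_MARKERS
    dedup: bool = True
    dedup_max_interval: Optional[float] = None
    min_valid_sessions: int = 2

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def validate(self) -> None:
        if self.threshold_mode not in ("fixed", "estimate"):
            raise ConfigError(
                f"threshold_mode must be 'fixed' or 'estimate', "
                f"got {self.threshold_mode!r}"
            )
        if self.audit_path is None:
            raise ConfigError("audit_path is required")
        if not Path(self.audit_path).exists():
            raise ConfigError(f"audit file not found: {self.audit_path}")
        if self.status_path is not None and not Path(self.status_path).exists():
            raise ConfigError(f"status file not found: {self.status_path}")


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, in memory."""

    threshold_seconds: float
    threshold_report: dict
    sessions: list[Session]
    session_metrics: list[SessionMetrics]
    patient_metrics: list[PatientMetrics]
    summary: dict
    status_summary: Optional[pd.DataFrame]
    quality: dict
    run_log: list[str]
    output_paths: dict = field(default_factory=dict)


def _stage(log: list[str], name: str, message: str) -> None:
    log.append(f"[{name}] {message}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline described by ``config``.

    Raises the stage's error annotated with the stage name; when an output
    directory is configured, files are only written after every stage has
    succeeded, so a failed run leaves no partial outputs.
    """
    config.validate()
    run_log: list[str] = []
    stage = "configuration"
    try:
        stage = "taxonomy"
        taxonomy = load_taxonomy(config.taxonomy_path)
        _stage(run_log, stage, f"{len(taxonomy.entries)} rules loaded")

        stage = "ingest"
        log = read_audit_log(config.audit_path, delimiter=config.delimiter)
        _stage(
            run_log, stage,
            f"{len(log)} records accepted, {len(log.rejected)} rejected",
        )

        stage = "canonical_sort"
        log = canonical_sort(log, taxonomy)
        _stage(run_log, stage, f"{len(log)} records ordered")

        stage = "threshold"
        gap_obs = gaps_mod.compute_gaps(log, taxonomy)
        threshold_report: dict
        if config.threshold_mode == "estimate":
            try:
                est = gaps_mod.estimate_threshold(
                    gap_obs, retention=config.retention, exclude_logouts=True
                )
                threshold = est.threshold_seconds
                threshold_report = {"mode": "estimate", **est.as_dict()}
            except EstimationError:
                threshold = float(config.threshold_seconds)
                threshold_report = {
                    "mode": "fallback_fixed",
                    "threshold_seconds": threshold,
                    "reason": "no usable gap observations",
                }
        else:
            threshold = float(config.threshold_seconds)
            threshold_report = {"mode": "fixed", "threshold_seconds": threshold}
        _stage(
            run_log, stage,
            f"{len(gap_obs)} gaps, threshold {threshold:.0f} s "
            f"({threshold_report['mode']})",
        )

        stage = "sessionize"
        sessions = assign_sessions(
            log, threshold, taxonomy, mobile_markers=config.mobile_markers
        )
        _stage(
            run_log, stage,
            f"{len(sessions)} sessions over "
            f"{sum(s.n_actions for s in sessions)} records",
        )

        stage = "dedup"
        if config.dedup:
            before = sum(s.n_actions for s in sessions)
            sessions = [
                dedup_actions(s, config.dedup_max_interval) for s in sessions
            ]
            after = sum(s.n_actions for s in sessions)
            _stage(run_log, stage, f"{before - after} duplicate records removed")
        else:
            _stage(run_log, stage, "skipped")

        stage = "metrics"
        sm = [session_metrics(s, taxonomy) for s in sessions]
        pm = patient_metrics(sm, min_valid_sessions=config.min_valid_sessions)
        summary = cohort_summary(pm, sm)
        _stage(
            run_log, stage,
            f"{summary['n_sessions_valid']}/{summary['n_sessions_total']} valid "
            f"sessions, {summary['n_active_patients']}/{summary['n_patients']} "
            f"active patients",
        )

        stage = "status"
        status_summary = None
        if config.status_path is not None:
            events = read_status_log(
                config.status_path, delimiter=config.delimiter
            )
            summaries = summarize_accounts(events)
            status_summary = status_table(summaries)
            _stage(run_log, stage, f"{len(summaries)} accounts summarized")
        else:
            _stage(run_log, stage, "no status file supplied")

        stage = "quality"
        quality = {
            "n_records": int(len(log)),
            "n_rejected_rows": int(len(log.rejected)),
            "rejected_rows": log.rejected.to_dict("records"),
            "n_unclassified_actions": int(sum(m.n_unclassified for m in sm)),
            "n_miscellaneous_actions": int(sum(m.n_miscellaneous for m in sm)),
        }
    except PortalSessionsError as err:
        raise type(err)(f"stage {stage!r}: {err}") from err

    result = PipelineResult(
        threshold_seconds=threshold,
        threshold_report=threshold_report,
        sessions=sessions,
        session_metrics=sm,
        patient_metrics=pm,
        summary=summary,
        status_summary=status_summary,
        quality=quality,
        run_log=run_log,
    )
    if config.out_dir is not None:
        result.output_paths = _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sessions": out_dir / "sessions.tsv",
        "patients": out_dir / "patients.tsv",
        "threshold": out_dir / "threshold.json",
        "summary": out_dir / "summary.json",
        "quality": out_dir / "quality.json",
        "run_log": out_dir / "run_log.txt",
    }
    session_metrics_frame(result.session_metrics).to_csv(
        paths["sessions"], sep="\t", index=False
    )
    patient_metrics_frame(result.patient_metrics).to_csv(
        paths["patients"], sep="\t", index=False
    )
    paths["threshold"].write_text(json.dumps(result.threshold_report, indent=2))
    paths["summary"].write_text(json.dumps(result.summary, indent=2, default=str))
    paths["quality"].write_text(json.dumps(result.quality, indent=2, default=str))
    paths["run_log"].write_text("\n".join(result.run_log) + "\n")
    if result.status_summary is not None:
        paths["status_table"] = out_dir / "status_table.tsv"
        result.status_summary.to_csv(paths["status_table"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
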