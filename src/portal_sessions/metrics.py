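"""Deduplication, frequency and comprehensiveness metrics, validity filters.

Usage is summarized along two dimensions at two levels:

* frequency of use -- how many times each portal function was accessed,
  per session and per patient;
* comprehensiveness of use -- how many distinct portal functions were
  accessed (0-8), per session and per patient.

Before counting, consecutive runs of identical records (same action type
and same extended info) within a session collapse to their first
occurrence: the mobile client re-logs the same action every ~2 seconds
while a page stays open, which inflates raw counts but not the time in
session (session durations are computed before deduplication and are left
untouched here).

Validity filters: a session is *valid* when its effective duration is
nonzero -- log-in attempts with no further navigation are discarded from
statistics; a patient is *active* with at least two valid sessions on
record.  Patient-level counts aggregate valid sessions only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .sessions import Session
from .taxonomy import METRIC_FUNCTIONS, ActionTaxonomy, PortalFunction

__all__ = [
    "SessionMetrics",
    "PatientMetrics",
    "dedup_actions",
    "session_metrics",
    "patient_metrics",
    "cohort_summary",
    "session_metrics_frame",
    "patient_metrics_frame",
]

MAX_COMPREHENSIVENESS = len(METRIC_FUNCTIONS)  # 8


@dataclass(frozen=True)
class SessionMetrics:
    """Per-session frequency counts and comprehensiveness."""

    session_id: str
    patient_id: str
    start_time: pd.Timestamp
    device: str
    duration_seconds: int
    function_counts: dict[PortalFunction, int]
    comprehensiveness: int
    is_valid: bool
    n_unclassified: int = 0
    n_miscellaneous: int = 0


@dataclass(frozen=True)
class PatientMetrics:
    """Per-patient aggregation over that patient's valid sessions."""

    patient_id: str
    n_sessions_total: int
    n_sessions_valid: int
    function_counts: dict[PortalFunction, int]
    comprehensiveness: int
    is_active: bool


def dedup_actions(session: Session, max_interval: Optional[float] = None) -> Session:
    """Collapse consecutive identical records to their first occurrence.

    Two records are identical when both action type and extended info
    match.  Non-consecutive repeats survive.  With ``max_interval`` set, a
    repeat only collapses when it follows its predecessor by at most that
    many seconds (off by default: the artifact is defined by value
    matching, not by timing).  Duration and device are preserved from the
    original session; idempotent by construction.
    """
    records = session.records
    if len(records) <= 1:
        return session
    action = records["action_type"].fillna("\x00")
    extended = records["extended_info"].fillna("\x00")
    same = action.eq(action.shift()) & extended.eq(extended.shift())
    if max_interval is not None:
        delta = records["timestamp"].diff().dt.total_seconds()
        same &= delta <= max_interval
    same = same.fillna(False)
    kept = records.loc[~same.to_numpy()].reset_index(drop=True)
    return replace(session, records=kept, n_actions=len(kept))


def session_metrics(session: Session, taxonomy: ActionTaxonomy) -> SessionMetrics:
    """Count classified, non-Miscellaneous actions per portal function.

    Unclassified records (raw strings the taxonomy does not cover) are
    excluded from counts and comprehensiveness but tallied in
    ``n_unclassified`` for the data-quality report; they are never dropped
    from the session itself.
    """
    counts: dict[PortalFunction, int] = {f: 0 for f in METRIC_FUNCTIONS}
    n_unclassified = 0
    n_misc = 0
    records = session.records
    for action, extended in zip(records["action_type"], records["extended_info"]):
        hit = taxonomy.match(
            None if pd.isna(action) else action,
            None if pd.isna(extended) else extended,
        )
        if hit is None:
            n_unclassified += 1
        elif hit.function is PortalFunction.MISCELLANEOUS:
            n_misc += 1
        else:
            counts[hit.function] += 1
    comprehensiveness = sum(1 for v in counts.values() if v > 0)
    return SessionMetrics(
        session_id=session.session_id,
        patient_id=session.patient_id,
        start_time=session.start_time,
        device=session.device,
        duration_seconds=session.duration_seconds,
        function_counts=counts,
        comprehensiveness=comprehensiveness,
        is_valid=session.duration_seconds > 0,
        n_unclassified=n_unclassified,
        n_miscellaneous=n_misc,
    )


def patient_metrics(
    sessions: Iterable[SessionMetrics],
    min_valid_sessions: int = 2,
) -> list[PatientMetrics]:
    """Aggregate session metrics to the patient level.

    Counts sum over *valid* sessions only; comprehensiveness is recomputed
    on the summed counts (so it is at least the maximum session-level
    comprehensiveness).  A patient is active with at least
    ``min_valid_sessions`` valid sessions.  Patients appear in first-seen
    order; a patient with zero sessions is simply absent.
    """
    order: list[str] = []
    total: dict[str, int] = {}
    valid: dict[str, int] = {}
    counts: dict[str, dict[PortalFunction, int]] = {}
    for sm in sessions:
        pid = sm.patient_id
        if pid not in total:
            order.append(pid)
            total[pid] = 0
            valid[pid] = 0
            counts[pid] = {f: 0 for f in METRIC_FUNCTIONS}
        total[pid] += 1
        if sm.is_valid:
            valid[pid] += 1
            for f, v in sm.function_counts.items():
                counts[pid][f] += v
    out = []
    for pid in order:
        comp = sum(1 for v in counts[pid].values() if v > 0)
        out.append(
            PatientMetrics(
                patient_id=pid,
                n_sessions_total=total[pid],
                n_sessions_valid=valid[pid],
                function_counts=counts[pid],
                comprehensiveness=comp,
                is_active=valid[pid] >= min_valid_sessions,
            )
        )
    return out


def _comprehensiveness_histogram(values: Sequence[int]) -> dict[int, int]:
    hist = {k: 0 for k in range(MAX_COMPREHENSIVENESS + 1)}
    for v in values:
        hist[int(v)] += 1
    return hist


def cohort_summary(
    patients: Sequence[PatientMetrics],
    sessions: Sequence[SessionMetrics],
    active_only: bool = False,
) -> dict:
    """Cohort-level descriptive summary.

    Session-level figures cover valid sessions; patient-level figures cover
    all patients with at least one session (or only active patients when
    ``active_only``).  ``fraction_multi_function`` is the share of valid
    sessions that touched more than one portal function.
    """
    valid = [s for s in sessions if s.is_valid]
    pats = [p for p in patients if p.is_active] if active_only else list(patients)
    session_hist = _comprehensiveness_histogram([s.comprehensiveness for s in valid])
    patient_hist = _comprehensiveness_histogram([p.comprehensiveness for p in pats])
    per_patient_counts = [p.n_sessions_valid for p in pats]
    if per_patient_counts:
        arr = np.asarray(per_patient_counts, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        count_stats = {
            "median": float(med),
            "iqr": float(q3 - q1),
            "max": int(arr.max()),
            "mean": float(arr.mean()),
        }
    else:
        count_stats = {"median": 0.0, "iqr": 0.0, "max": 0, "mean": 0.0}
    n_multi = sum(v for k, v in session_hist.items() if k >= 2)
    return {
        "n_sessions_total": len(sessions),
        "n_sessions_valid": len(valid),
        "n_patients": len(patients),
        "n_active_patients": sum(1 for p in patients if p.is_active),
        "sessions_per_patient": count_stats,
        "session_comprehensiveness_hist": session_hist,
        "patient_comprehensiveness_hist": patient_hist,
        "fraction_multi_function": (n_multi / len(valid)) if valid else 0.0,
    }


def session_metrics_frame(sessions: Iterable[SessionMetrics]) -> pd.DataFrame:
    """One row per session: identity, device, duration, the eight function
    counts, comprehensiveness and validity.  Column order is fixed."""
    rows = []
    for s in sessions:
        row = {
            "session_id": s.session_id,
            "patient_id": s.patient_id,
            "start_time": s.start_time,
            "device": s.device,
            "duration_seconds": s.duration_seconds,
        }
        for f in METRIC_FUNCTIONS:
            row[f.value] = s.function_counts[f]
        row["comprehensiveness"] = s.comprehensiveness
        row["is_valid"] = s.is_valid
        row["n_unclassified"] = s.n_unclassified
        rows.append(row)
    cols = (
        ["session_id", "patient_id", "start_time", "device", "duration_seconds"]
        + [f.value for f in METRIC_FUNCTIONS]
        + ["comprehensiveness", "is_valid", "n_unclassified"]
    )
    return pd.DataFrame(rows, columns=cols)


def patient_metrics_frame(patients: Iterable[PatientMetrics]) -> pd.DataFrame:
    """One row per patient with session counts, function counts and
    comprehensiveness.  Column order is fixed."""
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "n_sessions_total": p.n_sessions_total,
            "n_sessions_valid": p.n_sessions_valid,
        }
        for f in METRIC_FUNCTIONS:
            row[f.value] = p.function_counts[f]
        row["comprehensiveness"] = p.comprehensiveness
        row["is_active"] = p.is_active
        rows.append(row)
    cols = (
        ["patient_id", "n_sessions_total", "n_sessions_valid"]
        + [f.value for f in METRIC_FUNCTIONS]
        + ["comprehensiveness", "is_active"]
    )
    return pd.DataFrame(rows, columns=cols)
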