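"""Partitioning a patient's record stream into sessions.

A session is a coherent, limited, uninterrupted run of one patient's portal
actions.  Server-assigned session numbers are unreliable (absent in older
exports, intermittently tracked, occasionally spanning several days), so
sessionization here is rule-based over the canonically sorted stream and
ignores them entirely; the raw value is carried through for diagnostics.

A new session starts at:

(a) a patient's first record;
(b) any log-in record (an explicit re-login is a new engagement, even
    after a short gap);
(c) any record separated from its predecessor by strictly more than the
    inactivity threshold;
(d) the first record after a log-out.

A gap exactly equal to the threshold does not split.  Every record belongs
to exactly one session.

Each session carries a device label inferred from log-in metadata (mobile
client markers in the user agent or extended info) and an *effective*
duration that excludes log-out records, since server keep-alive log-outs
stamped ~20 minutes after the last real action would otherwise inflate idle
desktop sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .ingest import AuditLog
from .taxonomy import ActionTaxonomy

__all__ = [
    "DEFAULT_MOBILE_MARKERS",
    "Session",
    "assign_sessions",
    "infer_device",
    "session_duration",
    "sessions_to_frame",
]

#: Substrings (case-insensitive) of user_agent / extended_info that mark the
#: native mobile client.  Site-configurable; deployments differ.
DEFAULT_MOBILE_MARKERS: tuple[str, ...] = ("epicmychart",)


@dataclass
class Session:
    """One contiguous run of a patient's records.

    ``records`` is a DataFrame slice in canonical order carrying the audit
    columns plus ``is_login``/``is_logout`` flags.  ``duration_seconds`` is
    the effective time in session: last non-log-out timestamp minus first
    non-log-out timestamp, zero when fewer than two non-log-out records
    exist.  It is computed before deduplication (duplicate removal must not
    change the time in session).
    """

    session_id: str
    patient_id: str
    records: pd.DataFrame
    start_time: pd.Timestamp
    device: str
    duration_seconds: int
    n_actions: int


def infer_device(
    session: "Session | pd.DataFrame",
    mobile_markers: Sequence[str] = DEFAULT_MOBILE_MARKERS,
) -> str:
    """Infer the device a session originated from.

    ``mobile`` if any record's user agent or extended info contains a mobile
    marker; otherwise ``desktop`` if a log-in record carries a non-missing
    user agent free of mobile markers (first such log-in wins); ``unknown``
    when there is no evidence either way.
    """
    records = session.records if isinstance(session, Session) else session
    markers = tuple(m.casefold() for m in mobile_markers)

    def has_marker(value) -> bool:
        if pd.isna(value):
            return False
        folded = str(value).casefold()
        return any(m in folded for m in markers)

    for col in ("user_agent", "extended_info"):
        if records[col].map(has_marker).any():
            return "mobile"
    logins = records.loc[records["is_login"].astype(bool)]
    for agent in logins["user_agent"]:
        if not pd.isna(agent):
            return "desktop"
    return "unknown"


def session_duration(session: "Session | pd.DataFrame") -> int:
    """Effective time in session, in seconds, excluding log-out records."""
    records = session.records if isinstance(session, Session) else session
    kept = records.loc[~records["is_logout"].astype(bool), "timestamp"]
    if len(kept) < 2:
        return 0
    return int((kept.iloc[-1] - kept.iloc[0]).total_seconds())


def assign_sessions(
    log: AuditLog,
    threshold_seconds: float,
    taxonomy: ActionTaxonomy,
    mobile_markers: Sequence[str] = DEFAULT_MOBILE_MARKERS,
) -> list[Session]:
    """Partition a canonically sorted log into sessions.

    Returns one :class:`Session` per contiguous run, in order.  Session
    identifiers are deterministic: ``<patient_id>-S<ordinal>`` numbered per
    patient in time order.
    """
    if threshold_seconds <= 0:
        raise ParameterError(
            f"threshold_seconds must be positive, got {threshold_seconds}"
        )
    frame = log.frame
    if len(frame) == 0:
        return []

    uniques = frame["action_type"].dropna().unique()
    login_types = {a for a in uniques if taxonomy.is_login(a)}
    logout_types = {a for a in uniques if taxonomy.is_logout(a)}
    frame = frame.assign(
        is_login=frame["action_type"].isin(login_types).to_numpy(),
        is_logout=frame["action_type"].isin(logout_types).to_numpy(),
    )

    patient = frame["patient_id"].to_numpy()
    new_patient = np.ones(len(frame), dtype=bool)
    new_patient[1:] = patient[1:] != patient[:-1]

    delta = frame["timestamp"].diff().dt.total_seconds().to_numpy()
    within = ~new_patient
    if np.any(delta[within] < 0):
        raise ParameterError(
            "audit log is not canonically sorted; call canonical_sort first"
        )

    prev_logout = np.zeros(len(frame), dtype=bool)
    prev_logout[1:] = frame["is_logout"].to_numpy()[:-1]

    breaks = (
        new_patient
        | frame["is_login"].to_numpy()
        | (np.nan_to_num(delta, nan=np.inf) > threshold_seconds)
        | prev_logout
    )
    session_ordinal = np.cumsum(breaks)  # 1-based run index over the log
    frame = frame.assign(_run=session_ordinal)

    sessions: list[Session] = []
    per_patient_counter: dict[str, int] = {}
    for _, group in frame.groupby("_run", sort=True):
        pid = group["patient_id"].iloc[0]
        k = per_patient_counter.get(pid, 0) + 1
        per_patient_counter[pid] = k
        records = group.drop(columns="_run").reset_index(drop=True)
        duration = session_duration(records)
        sessions.append(
            Session(
                session_id=f"{pid}-S{k:05d}",
                patient_id=str(pid),
                records=records,
                start_time=records["timestamp"].iloc[0],
                device=infer_device(records, mobile_markers),
                duration_seconds=duration,
                n_actions=len(records),
            )
        )
    return sessions


def sessions_to_frame(sessions: Iterable[Session]) -> pd.DataFrame:
    """Flatten sessions back to one row per record, with session columns.

    Output = the audit columns plus ``session_id``, ``device`` and
    ``duration_seconds`` repeated on every record of the session.
    """
    parts = []
    for s in sessions:
        part = s.records.copy()
        part["session_id"] = s.session_id
        part["device"] = s.device
        part["duration_seconds"] = s.duration_seconds
        parts.append(part)
    if not parts:
        return pd.DataFrame(
            columns=[
                "patient_id", "timestamp", "action_type", "extended_info",
                "server_session", "user_agent", "input_index", "is_login",
                "is_logout", "session_id", "device", "duration_seconds",
            ]
        )
    return pd.concat(parts, ignore_index=True)
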