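"""Account-status histories: activation time and current status per patient.

A portal account moves through statuses over time -- *Pending activation*
during sign-up, *Activated* during regular use, *Inactivated* when use
ends (often because the patient died), and *Patient declined*.  The status
history export carries one row per status change with a timestamp, the
technology that made the change and a free-text comment.

Summarization keeps the earliest *Activated* event as the activation time,
the latest event's status as the current status, and flags deceased
patients by pattern-matching the comment of *Inactivated* events (the
exact wording is site configuration).  Patients with audit activity but no
status history -- users who never formally concluded sign-up yet produced
logs -- stay in the analysis with status ``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import SchemaError
from .ingest import TIMESTAMP_FORMAT, _normalize_text

__all__ = [
    "STATUS_CATEGORIES",
    "DEFAULT_DECEASED_PATTERN",
    "AccountSummary",
    "read_status_log",
    "summarize_account",
    "summarize_accounts",
    "status_table",
]

#: Canonical status vocabulary, in reporting order.
STATUS_CATEGORIES: tuple[str, ...] = (
    "Activated",
    "Inactivated",
    "Patient declined",
    "Pending activation",
)

DEFAULT_DECEASED_PATTERN = "deceased"

_STATUS_COLUMNS = {
    "patient_id": ("PAT_MRN_ID", "PT_MRN_ID", "MRN"),
    "status": ("MYC_STATUS_HX",),
    "timestamp": ("MYC_STATUS_TMSTP",),
    "method": ("MYC_STATUS_MTHD",),
    "comment": ("MYC_STATUS_CMT",),
}

_STATUS_ALIASES = {
    "activated": "Activated",
    "active": "Activated",
    "inactivated": "Inactivated",
    "inactive": "Inactivated",
    "patient declined": "Patient declined",
    "declined": "Patient declined",
    "pending activation": "Pending activation",
    "pending": "Pending activation",
}


@dataclass(frozen=True)
class AccountSummary:
    """Per-patient digest of the status history."""

    patient_id: str
    activation_time: Optional[pd.Timestamp]
    current_status: str
    deceased: bool
    n_events: int
    unknown_statuses: tuple[str, ...] = ()


def read_status_log(
    path: Union[str, Path],
    *,
    delimiter: str = "\t",
    encoding: str = "utf-8",
    timestamp_format: str = TIMESTAMP_FORMAT,
) -> pd.DataFrame:
    """Read a status-history export into a normalized DataFrame.

    Columns: patient_id, status, timestamp, method, comment.  Rows keep
    their input order (the tie rule for same-timestamp events).
    """
    raw = pd.read_csv(
        path, sep=delimiter, dtype=str, encoding=encoding, keep_default_na=False
    )
    lower = {h.strip().casefold(): h for h in raw.columns}
    resolved = {}
    missing = []
    for canonical, names in _STATUS_COLUMNS.items():
        for name in names:
            if name.casefold() in lower:
                resolved[canonical] = lower[name.casefold()]
                break
        else:
            missing.append(f"{canonical} (expected one of: {', '.join(names)})")
    if missing:
        raise SchemaError("missing required column(s): " + "; ".join(missing))
    frame = pd.DataFrame({c: raw[r] for c, r in resolved.items()})
    for col in ("patient_id", "status", "method", "comment"):
        frame[col] = _normalize_text(frame[col])
    frame["timestamp"] = pd.to_datetime(
        frame["timestamp"].astype("string").str.strip(),
        format=timestamp_format,
        errors="coerce",
    )
    frame["input_index"] = range(len(frame))
    return frame


def _canonical_status(value) -> tuple[str, bool]:
    """Map a raw status string to the canonical vocabulary.

    Returns (canonical_or_raw, recognized).  Unknown statuses are flagged,
    never dropped.
    """
    if pd.isna(value):
        return "unknown", False
    key = str(value).strip().casefold()
    if key in _STATUS_ALIASES:
        return _STATUS_ALIASES[key], True
    return str(value).strip(), False


def summarize_account(
    events: pd.DataFrame,
    deceased_pattern: str = DEFAULT_DECEASED_PATTERN,
) -> Optional[AccountSummary]:
    """Digest one patient's ordered status events.

    Activation time is the earliest *Activated* event's timestamp (absent
    if the account was never activated); current status is the latest
    event's (ties resolved by input order, last wins); deceased is set when
    any *Inactivated* event's comment contains ``deceased_pattern``
    (case-insensitive).  Returns ``None`` for an empty event list: the
    patient never registered.
    """
    if len(events) == 0:
        return None
    pids = events["patient_id"].dropna().unique()
    if len(pids) != 1:
        raise ValueError(f"events must belong to one patient, got {list(pids)}")
    ev = events.sort_values(["timestamp", "input_index"], kind="mergesort")
    canon = [_canonical_status(s) for s in ev["status"]]
    statuses = [c[0] for c in canon]
    unknown = tuple(sorted({s for s, ok in zip(statuses, (c[1] for c in canon)) if not ok}))

    activation = None
    deceased = False
    pattern = deceased_pattern.casefold()
    for status, ts, comment in zip(statuses, ev["timestamp"], ev["comment"]):
        if status == "Activated" and activation is None and not pd.isna(ts):
            activation = ts
        if status == "Inactivated" and not pd.isna(comment):
            if pattern in str(comment).casefold():
                deceased = True
    return AccountSummary(
        patient_id=str(pids[0]),
        activation_time=activation,
        current_status=statuses[-1],
        deceased=deceased,
        n_events=len(ev),
        unknown_statuses=unknown,
    )


def summarize_accounts(
    events: pd.DataFrame,
    deceased_pattern: str = DEFAULT_DECEASED_PATTERN,
) -> list[AccountSummary]:
    """One :class:`AccountSummary` per patient present in the event table."""
    out = []
    for _, group in events.groupby("patient_id", sort=True):
        summary = summarize_account(group, deceased_pattern)
        if summary is not None:
            out.append(summary)
    return out


def status_table(summaries: Sequence[AccountSummary]) -> pd.DataFrame:
    """Counts and percentages of current account status.

    Canonical categories come first in reporting order; any other observed
    statuses (including ``unknown``) follow alphabetically.  Percentages
    sum to 100 up to rounding.
    """
    if not summaries:
        return pd.DataFrame(columns=["status", "n", "percent"])
    counts: dict[str, int] = {}
    for s in summaries:
        counts[s.current_status] = counts.get(s.current_status, 0) + 1
    ordered = [c for c in STATUS_CATEGORIES if c in counts]
    ordered += sorted(k for k in counts if k not in STATUS_CATEGORIES)
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "status": ordered,
            "n": [counts[c] for c in ordered],
            "percent": [100.0 * counts[c] / total for c in ordered],
        }
    )
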