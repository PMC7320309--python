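"""Reading, normalizing and canonically ordering raw audit-log exports.

The expected input is a delimited text export of the portal's user-access
audit table with six columns: a patient identifier (PAT_MRN_ID), an action
timestamp at one-second resolution (UA_TIME), a raw action-type string
(MYC_UA_TYPE_C), optional extended action information (UA_EXTENDED_INFO), a
server-assigned session number (UA_SESSION_NUM) and the client user agent
(UA_USER_AGENT).  Column matching is case-insensitive and alias-configurable
since export conventions differ between sites.

Free-text fields are trimmed and the literal strings ``Null``/``NULL``/empty
normalize to an explicit missing value.  Rows whose timestamp does not parse
are rejected into a report carried on the :class:`AuditLog` (never silently
dropped).  Timestamps are timezone-naive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import SchemaError
from .taxonomy import ActionTaxonomy

__all__ = [
    "CANONICAL_COLUMNS",
    "DEFAULT_ALIASES",
    "TIMESTAMP_FORMAT",
    "AuditLog",
    "read_audit_log",
    "write_audit_log",
    "canonical_sort",
]

#: canonical column name -> default raw header aliases (case-insensitive)
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "patient_id": ("PAT_MRN_ID", "PT_MRN_ID", "MRN"),
    "timestamp": ("UA_TIME",),
    "action_type": ("MYC_UA_TYPE_C",),
    "extended_info": ("UA_EXTENDED_INFO",),
    "server_session": ("UA_SESSION_NUM",),
    "user_agent": ("UA_USER_AGENT",),
}

CANONICAL_COLUMNS = tuple(DEFAULT_ALIASES)

#: default on-disk raw header names used when writing
RAW_HEADERS: dict[str, str] = {c: a[0] for c, a in DEFAULT_ALIASES.items()}

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"

_NULL_TOKENS = {"", "null", "none", "na", "n/a"}


@dataclass
class AuditLog:
    """An ordered collection of normalized audit records.

    ``frame`` holds one row per accepted record with the canonical columns
    (patient_id, timestamp, action_type, extended_info, server_session,
    user_agent) plus ``input_index``, the zero-based position of the row in
    the source file, which keeps sorting stable and rejected-row reports
    addressable.  ``rejected`` reports rows that failed validation, with
    their row number and reason.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["input_index", "reason"])
    )
    sorted: bool = False

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    def copy(self) -> "AuditLog":
        return AuditLog(
            frame=self.frame.copy(),
            provenance=dict(self.provenance),
            rejected=self.rejected.copy(),
            sorted=self.sorted,
        )


def _empty_frame() -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "patient_id": pd.Series(dtype="string"),
            "timestamp": pd.Series(dtype="datetime64[ns]"),
            "action_type": pd.Series(dtype="string"),
            "extended_info": pd.Series(dtype="string"),
            "server_session": pd.Series(dtype="string"),
            "user_agent": pd.Series(dtype="string"),
            "input_index": pd.Series(dtype="int64"),
        }
    )
    return frame


def _normalize_text(series: pd.Series) -> pd.Series:
    s = series.astype("string").str.strip()
    return s.mask(s.str.casefold().isin(_NULL_TOKENS))


def _resolve_columns(
    header: list[str], aliases: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    lower = {h.strip().casefold(): h for h in header}
    resolved: dict[str, str] = {}
    missing: list[str] = []
    for canonical, names in aliases.items():
        for name in names:
            if name.casefold() in lower:
                resolved[canonical] = lower[name.casefold()]
                break
        else:
            missing.append(f"{canonical} (expected one of: {', '.join(names)})")
    if missing:
        raise SchemaError("missing required column(s): " + "; ".join(missing))
    return resolved


def read_audit_log(
    path: Union[str, Path],
    *,
    delimiter: str = "\t",
    encoding: str = "utf-8",
    timestamp_format: str = TIMESTAMP_FORMAT,
    aliases: Optional[Mapping[str, tuple[str, ...]]] = None,
) -> AuditLog:
    """Read a delimited audit-log export into a normalized :class:`AuditLog`.

    Raises :class:`SchemaError` when a required column is absent.  Rows with
    unparseable timestamps are diverted to ``log.rejected`` together with
    their zero-based data-row number and a reason.  A file with a header and
    no data rows yields an empty log.
    """
    path = Path(path)
    aliases = dict(DEFAULT_ALIASES) | dict(aliases or {})
    raw = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        encoding=encoding,
        keep_default_na=False,
        skip_blank_lines=False,
    )
    provenance = {
        "path": str(path),
        "delimiter": delimiter,
        "encoding": encoding,
        "timestamp_format": timestamp_format,
    }
    if raw.empty:
        resolved = _resolve_columns(list(raw.columns), aliases)
        return AuditLog(frame=_empty_frame(), provenance=provenance)
    resolved = _resolve_columns(list(raw.columns), aliases)
    frame = pd.DataFrame({c: raw[resolved[c]] for c in CANONICAL_COLUMNS})
    frame["input_index"] = np.arange(len(frame), dtype="int64")

    for col in ("patient_id", "action_type", "extended_info", "server_session",
                "user_agent"):
        frame[col] = _normalize_text(frame[col])
    ts = pd.to_datetime(
        frame["timestamp"].astype("string").str.strip(),
        format=timestamp_format,
        errors="coerce",
    )
    bad = ts.isna()
    rejected = pd.DataFrame(
        {
            "input_index": frame.loc[bad, "input_index"].to_numpy(),
            "reason": [
                f"unparseable timestamp: {v!r}"
                for v in frame.loc[bad, "timestamp"]
            ],
        }
    )
    frame = frame.loc[~bad].copy()
    frame["timestamp"] = ts[~bad]
    frame = frame.reset_index(drop=True)
    return AuditLog(frame=frame, provenance=provenance, rejected=rejected)


def write_audit_log(
    log: AuditLog,
    path: Union[str, Path],
    *,
    delimiter: str = "\t",
    timestamp_format: str = TIMESTAMP_FORMAT,
) -> Path:
    """Write an :class:`AuditLog` back to disk in the raw column schema.

    Missing values are emitted as the literal ``Null`` used by the source
    system, so a write/read round trip preserves the record multiset.
    """
    path = Path(path)
    out = pd.DataFrame()
    for canonical, raw_name in RAW_HEADERS.items():
        if canonical == "timestamp":
            out[raw_name] = log.frame["timestamp"].dt.strftime(timestamp_format)
        else:
            out[raw_name] = log.frame[canonical].fillna("Null")
    out.to_csv(path, sep=delimiter, index=False)
    return path


def canonical_sort(log: AuditLog, taxonomy: Optional[ActionTaxonomy] = None) -> AuditLog:
    """Totally order records by (patient, timestamp, tie rank, input order).

    Within one patient-second, log-in attempts sort first (establishing a
    logical order for co-occurrent events) and log-outs last; remaining ties
    keep stable input order.  Idempotent, and invariant to any permutation
    of the input rows up to fully identical rows.
    """
    frame = log.frame
    if taxonomy is not None:
        action = frame["action_type"]
        uniques = action.dropna().unique()
        login = {a for a in uniques if taxonomy.is_login(a)}
        logout = {a for a in uniques if taxonomy.is_logout(a)}
        is_login = action.isin(login)
        is_logout = action.isin(logout)
    else:
        folded = frame["action_type"].str.strip().str.casefold()
        is_login = folded.isin(("login", "log in"))
        is_logout = folded.isin(("logout", "log out"))
    tie_rank = np.ones(len(frame), dtype="int8")
    tie_rank[is_login.fillna(False).to_numpy()] = 0
    tie_rank[is_logout.fillna(False).to_numpy()] = 2
    frame = frame.assign(_tie_rank=tie_rank)
    # After the tie rank, remaining field values break ties so the order is
    # invariant to input permutation; input_index only orders identical rows.
    frame = frame.sort_values(
        [
            "patient_id",
            "timestamp",
            "_tie_rank",
            "action_type",
            "extended_info",
            "server_session",
            "user_agent",
            "input_index",
        ],
        kind="mergesort",
    ).drop(columns="_tie_rank")
    out = AuditLog(
        frame=frame.reset_index(drop=True),
        provenance=dict(log.provenance),
        rejected=log.rejected.copy(),
        sorted=True,
    )
    return out
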