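"""Two-level taxonomy mapping raw audit-log action types to portal functions.

Outpatient-portal audit logs record one row per user action, identified by a
raw action-type string (and sometimes an extended-info string).  Analysis
groups those actions under eight portal functions -- Messaging, Visits,
My record, Medical tools, Billing, Resources, Proxy, Preferences -- plus a
Miscellaneous bucket for auxiliary events (log-in, log-out, two-factor
authentication) that are flagged for sessionization but excluded from usage
metrics.

The raw-string vocabulary is site- and version-dependent, so the mapping is
configuration, not code: the packaged default (``data/taxonomy.yaml``) ships
the canonical 44 action labels plus a site-editable section of raw log
strings, and institutions are expected to extend the raw section for their
own deployment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .errors import TaxonomyError

__all__ = [
    "PortalFunction",
    "METRIC_FUNCTIONS",
    "TaxonomyEntry",
    "Classification",
    "ActionTaxonomy",
    "load_taxonomy",
    "default_taxonomy_path",
    "categorize",
]


class PortalFunction(str, Enum):
    """Top level of the taxonomy: the portal's functional areas."""

    MESSAGING = "Messaging"
    VISITS = "Visits"
    MY_RECORD = "My record"
    MEDICAL_TOOLS = "Medical tools"
    BILLING = "Billing"
    RESOURCES = "Resources"
    PROXY = "Proxy"
    PREFERENCES = "Preferences"
    MISCELLANEOUS = "Miscellaneous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The eight functions that contribute to usage metrics (Miscellaneous is
#: flagged for sessionization only and never counted).
METRIC_FUNCTIONS: tuple[PortalFunction, ...] = tuple(
    f for f in PortalFunction if f is not PortalFunction.MISCELLANEOUS
)

MISC_FLAGS = ("login", "logout", "two_factor")


def _norm(text: Optional[str]) -> str:
    return "" if text is None else str(text).strip().casefold()


@dataclass(frozen=True)
class TaxonomyEntry:
    """One classification rule.

    A record matches when its action type matches one of ``patterns``
    (case-insensitive on trimmed strings; substring containment if
    ``substring`` is set) and, when ``extended`` is non-empty, its
    extended-info matches one of those patterns too.  A ``fallback`` entry
    matches only when no sibling entry with the same action pattern matched
    on extended-info, which keeps every record matched by at most one rule.
    """

    label: str
    function: PortalFunction
    patterns: tuple[str, ...]
    extended: tuple[str, ...] = ()
    substring: bool = False
    fallback: bool = False
    misc_flag: Optional[str] = None

    def matches_action(self, action: str) -> bool:
        if self.substring:
            return any(p in action for p in self.patterns)
        return action in self.patterns

    def matches_extended(self, extended: str) -> bool:
        if not self.extended:
            return True
        return extended in self.extended


@dataclass(frozen=True)
class Classification:
    """Resolved (action label, portal function) for one record."""

    label: str
    function: PortalFunction


@dataclass
class ActionTaxonomy:
    """Validated collection of classification rules plus auxiliary flags."""

    entries: list[TaxonomyEntry]
    source: Optional[str] = None
    _cache: dict[tuple[str, str], Optional[Classification]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        for e in self.entries:
            if e.misc_flag is not None and e.misc_flag not in MISC_FLAGS:
                raise TaxonomyError(
                    f"entry {e.label!r}: unknown miscellaneous flag {e.misc_flag!r}"
                )
            if e.misc_flag is not None and e.function is not PortalFunction.MISCELLANEOUS:
                raise TaxonomyError(
                    f"entry {e.label!r}: flagged entries must map to Miscellaneous"
                )
            if not e.patterns:
                raise TaxonomyError(f"entry {e.label!r} has no action patterns")
        n = len(self.entries)
        for i in range(n):
            for j in range(i + 1, n):
                self._check_pair(self.entries[i], self.entries[j])

    @staticmethod
    def _actions_overlap(a: TaxonomyEntry, b: TaxonomyEntry) -> bool:
        if a.substring or b.substring:
            # a substring pattern overlaps any pattern containing it
            return any(
                (p in q) or (q in p) for p in a.patterns for q in b.patterns
            )
        return bool(set(a.patterns) & set(b.patterns))

    @classmethod
    def _check_pair(cls, a: TaxonomyEntry, b: TaxonomyEntry) -> None:
        if not cls._actions_overlap(a, b):
            return
        if a.fallback and b.fallback:
            raise TaxonomyError(
                f"entries {a.label!r} and {b.label!r}: two fallback rules share "
                f"an action pattern"
            )
        if a.fallback or b.fallback:
            return  # fallback defers to the refined sibling: unambiguous
        if not a.extended and not b.extended:
            raise TaxonomyError(
                f"entries {a.label!r} and {b.label!r} both match the same action "
                f"pattern without extended-info refinement"
            )
        if a.extended and b.extended and set(a.extended) & set(b.extended):
            raise TaxonomyError(
                f"entries {a.label!r} and {b.label!r} share an extended-info "
                f"pattern"
            )
        if bool(a.extended) != bool(b.extended):
            raise TaxonomyError(
                f"entries {a.label!r} and {b.label!r}: a bare rule shadows a "
                f"refined one; mark the bare rule as fallback"
            )

    # -- matching --------------------------------------------------------

    def match(
        self, action_type: Optional[str], extended_info: Optional[str] = None
    ) -> Optional[Classification]:
        """Classify one (action type, extended info) pair.

        Returns ``None`` for records the taxonomy does not cover
        (the caller reports those as Unclassified, never drops them).
        """
        key = (_norm(action_type), _norm(extended_info))
        if key not in self._cache:
            self._cache[key] = self._match_uncached(*key)
        return self._cache[key]

    def _match_uncached(self, action: str, extended: str) -> Optional[Classification]:
        fallback: Optional[TaxonomyEntry] = None
        for e in self.entries:
            if not e.matches_action(action):
                continue
            if e.fallback:
                fallback = e
                continue
            if e.matches_extended(extended):
                return Classification(e.label, e.function)
        if fallback is not None:
            return Classification(fallback.label, fallback.function)
        return None

    # -- auxiliary-event flags ------------------------------------------

    def _has_flag(self, action_type: Optional[str], flag: str) -> bool:
        action = _norm(action_type)
        for e in self.entries:
            if e.misc_flag == flag and e.matches_action(action):
                return True
        return False

    def is_login(self, action_type: Optional[str]) -> bool:
        return self._has_flag(action_type, "login")

    def is_logout(self, action_type: Optional[str]) -> bool:
        return self._has_flag(action_type, "logout")

    def is_two_factor(self, action_type: Optional[str]) -> bool:
        return self._has_flag(action_type, "two_factor")

    # -- introspection ---------------------------------------------------

    @property
    def labels(self) -> set[tuple[str, PortalFunction]]:
        """Distinct (label, function) pairs excluding Miscellaneous."""
        return {
            (e.label, e.function)
            for e in self.entries
            if e.function is not PortalFunction.MISCELLANEOUS
        }

    def labels_by_function(self) -> dict[PortalFunction, set[str]]:
        out: dict[PortalFunction, set[str]] = {}
        for label, function in self.labels:
            out.setdefault(function, set()).add(label)
        return out


# -- loading -------------------------------------------------------------


def default_taxonomy_path() -> Path:
    """Path of the packaged default taxonomy configuration."""
    return Path(str(resources.files("portal_sessions").joinpath("data/taxonomy.yaml")))


def _parse_entry(
    raw: Mapping, function: PortalFunction, *, context: str
) -> TaxonomyEntry:
    if not isinstance(raw, Mapping) or "label" not in raw:
        raise TaxonomyError(f"{context}: every entry needs a 'label'")
    label = str(raw["label"])
    patterns = raw.get("match", [label])
    if isinstance(patterns, str):
        patterns = [patterns]
    extended = raw.get("extended", [])
    if isinstance(extended, str):
        extended = [extended]
    return TaxonomyEntry(
        label=label,
        function=function,
        patterns=tuple(_norm(p) for p in patterns),
        extended=tuple(_norm(p) for p in extended),
        substring=bool(raw.get("substring", False)),
        fallback=bool(raw.get("fallback", False)),
        misc_flag=raw.get("flag"),
    )


def load_taxonomy(path: Union[str, Path, None] = None) -> ActionTaxonomy:
    """Load and validate a taxonomy configuration.

    With no argument, loads the packaged default, which encodes the
    canonical 44 action labels across the 8 portal functions plus the
    Miscellaneous auxiliary events and a raw-log-string section.
    """
    if path is None:
        path = default_taxonomy_path()
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    entries: list[TaxonomyEntry] = []
    functions = doc.get("functions", {})
    known = {f.value: f for f in PortalFunction}
    for fname, items in functions.items():
        if fname not in known:
            raise TaxonomyError(f"unknown portal function {fname!r}")
        for raw in items or []:
            entries.append(_parse_entry(raw, known[fname], context=fname))
    for raw in doc.get("miscellaneous", []) or []:
        e = _parse_entry(raw, PortalFunction.MISCELLANEOUS, context="miscellaneous")
        entries.append(e)
    return ActionTaxonomy(entries=entries, source=str(path))


def categorize(
    record, taxonomy: ActionTaxonomy
) -> Optional[Classification]:
    """Classify one audit record (anything with .action_type/.extended_info
    attributes or a mapping with those keys).  Returns ``None`` when the
    record is Unclassified."""
    if isinstance(record, Mapping):
        action, extended = record.get("action_type"), record.get("extended_info")
    else:
        action = getattr(record, "action_type")
        extended = getattr(record, "extended_info", None)
    return taxonomy.match(action, extended)
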