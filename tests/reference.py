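"""Independent naive oracles used to cross-check the pipeline.

Deliberately written as plain single-pass loops over record lists, with no
shared code with the package implementation, so agreement is evidence and
not tautology.
"""

from __future__ import annotations

from datetime import datetime, timedelta
from typing import Sequence


def naive_sessionize(
    records: Sequence[dict],
    threshold_seconds: float,
    login_labels: frozenset = frozenset({"login"}),
    logout_labels: frozenset = frozenset({"logout"}),
) -> list[list[int]]:
    """Partition canonically sorted records into sessions; returns lists of
    record indices.

    Rules: a session starts at a patient's first record, at any log-in, at
    any record whose gap from the previous record strictly exceeds the
    threshold, and at the first record after a log-out.
    """
    partitions: list[list[int]] = []
    current: list[int] = []
    prev_patient = None
    prev_time: datetime | None = None
    prev_was_logout = False
    for i, rec in enumerate(records):
        action = (rec["action_type"] or "").strip().lower()
        is_login = action in login_labels
        start = False
        if rec["patient_id"] != prev_patient:
            start = True
        elif is_login:
            start = True
        elif prev_was_logout:
            start = True
        elif (rec["timestamp"] - prev_time).total_seconds() > threshold_seconds:
            start = True
        if start and current:
            partitions.append(current)
            current = []
        current.append(i)
        prev_patient = rec["patient_id"]
        prev_time = rec["timestamp"]
        prev_was_logout = action in logout_labels
    if current:
        partitions.append(current)
    return partitions


def sorted_quantile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation quantile computed by explicit sort-and-index."""
    xs = sorted(values)
    if not xs:
        raise ValueError("empty")
    pos = q * (len(xs) - 1)
    lo = int(pos)
    hi = min(lo + 1, len(xs) - 1)
    frac = pos - lo
    return xs[lo] * (1.0 - frac) + xs[hi] * frac


def random_log_rows(rng, n_max: int = 200, n_patients_max: int = 4) -> list[dict]:
    """Random small audit stream with gaps straddling a ~1000 s threshold.

    Returns canonically sorted rows (per-patient increasing timestamps) as
    dicts with patient_id / timestamp / action_type / extended_info.
    """
    actions = [
        "Login", "Logout", "Messaging", "Visits", "Test results",
        "Allergies", "Bill payment", "Notifications",
    ]
    base = datetime(2018, 1, 1)
    rows: list[dict] = []
    n_patients = 1 + int(rng.integers(n_patients_max))
    total = int(rng.integers(1, n_max + 1))
    for p in range(n_patients):
        pid = f"Q{p:03d}"
        t = base + timedelta(seconds=int(rng.integers(0, 10000)))
        n = max(1, total // n_patients)
        for _ in range(n):
            # gaps concentrated around the threshold so both branches of
            # the strictly-greater rule get exercised
            gap = int(rng.choice([0, 1, 2, 30, 500, 999, 1000, 1001, 1500, 5000]))
            t = t + timedelta(seconds=gap)
            action = actions[int(rng.integers(len(actions)))]
            rows.append(
                {
                    "patient_id": pid,
                    "timestamp": t,
                    "action_type": action,
                    "extended_info": None,
                }
            )
    rows.sort(key=lambda r: (r["patient_id"], r["timestamp"]))
    return rows
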