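"""Synthetic audit-log and status-history generator with ground truth.

No public corpus of portal audit logs exists (they are protected health
information), so every stage of the pipeline is exercised against synthetic
cohorts whose true structure is known by construction.  The generator emits
the same delimited schema as a real export -- PAT_MRN_ID, UA_TIME,
MYC_UA_TYPE_C, UA_EXTENDED_INFO, UA_SESSION_NUM, UA_USER_AGENT plus the
five status-history columns -- together with a :class:`GroundTruth` table
of true session boundaries, per-session function counts, devices and
account statuses.

The emitted data mimic the statistical structure of real portal logs:
an approximately log-normal body of within-session inter-action gaps,
heavy-tailed between-session gaps, right-skewed session counts per
patient, predominantly single-function sessions, and -- switchable -- the
two artifact classes real exports carry:

* **keep-alive log-outs**: idle desktop sessions are closed by a
  server-stamped log-out ~21 minutes (default 1210-1310 s) after the last
  real action, producing a spurious spike in the gap distribution near
  twenty minutes and a bimodal raw session-duration distribution;
* **mobile duplicate bursts**: the mobile client re-logs the open page's
  action every 2 seconds, inflating raw action counts.

Unreliable server session numbers are also emulated (numbers missing
before a cutover date; numbers reused across sessions days apart), since
the pipeline must ignore them.

All timestamps are quantized to whole seconds, matching the one-second
resolution of the audit table.  Output is fully determined by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gaps import DEFAULT_THRESHOLD_SECONDS
from .metrics import PatientMetrics
from .sessions import Session
from .taxonomy import METRIC_FUNCTIONS, load_taxonomy

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "RecoveryReport",
    "simulate_cohort",
    "score_recovery",
]

MOBILE_AGENTS = ("EpicMyChart-iPhone", "EpicMyChart-Android")
DESKTOP_AGENT = "Mozilla/5.0 (Windows NT 10.0; Win64; x64) AppleWebKit/537.36"

#: Default share of sessions touching each portal function, loosely shaped
#: like observed cohorts: messaging and record review dominate, billing is
#: moderate, tools/proxy/preferences are rare, educational resources leave
#: no captured trace at all.
DEFAULT_FUNCTION_MIXTURE: dict[str, float] = {
    "Messaging": 0.34,
    "Visits": 0.21,
    "My record": 0.31,
    "Medical tools": 0.01,
    "Billing": 0.08,
    "Resources": 0.0,
    "Proxy": 0.015,
    "Preferences": 0.035,
}

#: Default account-status mixture (shares of patients by final status).
DEFAULT_STATUS_MIXTURE: dict[str, float] = {
    "Activated": 0.9398,
    "Inactivated": 0.0534,
    "Patient declined": 0.0016,
    "Pending activation": 0.0052,
}


@dataclass
class SimConfig:
    """Cohort-generation parameters.  The defaults are the study conditions
    used throughout the test suite; see the methods note for rationale."""

    n_patients: int = 200
    seed: int = 0
    # sessions per patient = 1 + NegBinom(n, p): right-skewed, mean ~9
    sessions_nbinom_n: float = 1.5
    sessions_nbinom_p: float = 0.158
    # actions per session (after the log-in) = 1 + NegBinom(n, p): mean ~2.5
    actions_nbinom_n: float = 1.0
    actions_nbinom_p: float = 0.4
    # within-session inter-action gap (s): lognormal, rounded to whole
    # seconds, clamped to [1, threshold]
    within_gap_meanlog: float = math.log(45.0)
    within_gap_sdlog: float = 1.1
    # between-session gap (s) = threshold + 1 + round(lognormal): hours-days
    between_gap_meanlog: float = math.log(20000.0)
    between_gap_sdlog: float = 1.0
    threshold_seconds: float = DEFAULT_THRESHOLD_SECONDS
    function_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FUNCTION_MIXTURE)
    )
    # probability each action repeats the session's primary function
    p_primary: float = 0.85
    p_mobile: float = 0.4
    p_missing_agent: float = 0.05
    # -- artifact switches ------------------------------------------------
    keepalive_logout: bool = False
    p_idle_desktop: float = 0.5
    keepalive_delay_min: int = 1210
    keepalive_delay_max: int = 1310
    mobile_duplicates: bool = False
    p_burst: float = 0.3
    burst_mean_length: float = 3.0
    missing_session_num_before: Optional[str] = None
    multiday_session_num: float = 0.0
    # -- status history ---------------------------------------------------
    status_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_MIXTURE)
    )
    p_deceased_given_inactivated: float = 0.93
    start_date: str = "2017-01-01"

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        for name, mixture in (
            ("function_mixture", self.function_mixture),
            ("status_mixture", self.status_mixture),
        ):
            vals = list(mixture.values())
            if any(v < 0 or v > 1 for v in vals):
                raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-6:
                raise ConfigError(f"{name}: probabilities must sum to 1")
        known = {f.value for f in METRIC_FUNCTIONS}
        unknown = set(self.function_mixture) - known
        if unknown:
            raise ConfigError(f"function_mixture: unknown functions {unknown}")
        for p in (self.p_primary, self.p_mobile, self.p_missing_agent,
                  self.p_idle_desktop, self.p_burst,
                  self.p_deceased_given_inactivated, self.multiday_session_num):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.threshold_seconds <= 0:
            raise ConfigError("threshold_seconds must be positive")
        if self.keepalive_delay_min > self.keepalive_delay_max:
            raise ConfigError("keepalive delay range is inverted")


@dataclass
class GroundTruth:
    """True cohort structure, consistent with the emitted files.

    ``sessions``: one row per true session with patient_id, session_index,
    start_time, device, has_agent (a log-in user agent was emitted),
    idle_keepalive, n_actions and one count column per portal function
    (pre-artifact counts).  ``status``: one row per patient with the true
    final status, activation flag and deceased flag.
    """

    sessions: pd.DataFrame
    status: pd.DataFrame

    def patient_function_counts(self) -> pd.DataFrame:
        cols = [f.value for f in METRIC_FUNCTIONS]
        if self.sessions.empty:
            return pd.DataFrame(columns=cols)
        return self.sessions.groupby("patient_id")[cols].sum()


@dataclass
class SimResult:
    """Generator output: the two raw frames plus the ground truth."""

    audit: pd.DataFrame
    status: pd.DataFrame
    truth: GroundTruth
    config: SimConfig

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        """Write audit/status exports and ground-truth tables as TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "audit": out_dir / "audit.tsv",
            "status": out_dir / "status.tsv",
            "truth_sessions": out_dir / "truth_sessions.tsv",
            "truth_status": out_dir / "truth_status.tsv",
        }
        self.audit.to_csv(paths["audit"], sep="\t", index=False)
        self.status.to_csv(paths["status"], sep="\t", index=False)
        self.truth.sessions.to_csv(paths["truth_sessions"], sep="\t", index=False)
        self.truth.status.to_csv(paths["truth_status"], sep="\t", index=False)
        return paths


def _draw_gap(rng: np.random.Generator, meanlog: float, sdlog: float,
              lo: float, hi: float) -> int:
    g = int(round(float(rng.lognormal(meanlog, sdlog))))
    return int(min(max(g, lo), hi))


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate one cohort; fully deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    base = pd.Timestamp(config.start_date)
    taxonomy = load_taxonomy()
    labels_by_fn = {
        fn.value: sorted(labels)
        for fn, labels in taxonomy.labels_by_function().items()
    }

    fn_names = [f.value for f in METRIC_FUNCTIONS]
    fn_probs = np.array([config.function_mixture.get(n, 0.0) for n in fn_names])
    fn_probs = fn_probs / fn_probs.sum()

    status_names = list(config.status_mixture)
    status_probs = np.array([config.status_mixture[n] for n in status_names])
    status_probs = status_probs / status_probs.sum()

    missing_cut = (
        pd.Timestamp(config.missing_session_num_before)
        if config.missing_session_num_before
        else None
    )

    audit_rows: list[tuple] = []  # (pid, t, action, extended, agent, srv)
    truth_rows: list[dict] = []
    status_rows: list[tuple] = []
    truth_status_rows: list[dict] = []
    server_counter = 500000

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        n_sessions = 1 + int(rng.negative_binomial(
            config.sessions_nbinom_n, config.sessions_nbinom_p))
        t = int(rng.integers(0, 365 * 86400))  # patient's first log-in

        # -- status history ------------------------------------------------
        final_status = status_names[int(rng.choice(len(status_names), p=status_probs))]
        reg_t = max(0, t - int(rng.integers(3600, 30 * 86400)))
        deceased = False
        events = [(reg_t, "Pending activation", "WEB", None)]
        if final_status != "Pending activation":
            act_t = reg_t + int(rng.integers(60, 86400))
            if final_status == "Patient declined":
                events.append((act_t, "Patient declined", "WEB", None))
            else:
                events.append((act_t, "Activated", "MYCHART", None))
                if final_status == "Inactivated":
                    deceased = bool(
                        rng.random() < config.p_deceased_given_inactivated
                    )
                    comment = "patient deceased" if deceased else "closed by request"
                    events.append(
                        (act_t + int(rng.integers(86400, 700 * 86400)),
                         "Inactivated", "EHR", comment)
                    )
        for ev_t, ev_status, ev_method, ev_comment in events:
            status_rows.append((pid, ev_status, ev_t, ev_method, ev_comment))
        truth_status_rows.append(
            {
                "patient_id": pid,
                "current_status": final_status,
                "activated": final_status in ("Activated", "Inactivated"),
                "deceased": deceased,
            }
        )

        # -- sessions ------------------------------------------------------
        prev_server: Optional[int] = None
        for k in range(n_sessions):
            mobile = bool(rng.random() < config.p_mobile)
            has_agent = not bool(rng.random() < config.p_missing_agent)
            if mobile:
                agent = MOBILE_AGENTS[int(rng.integers(len(MOBILE_AGENTS)))]
            else:
                agent = DESKTOP_AGENT
            if not has_agent:
                agent = None

            server_counter += 1
            if prev_server is not None and rng.random() < config.multiday_session_num:
                srv = prev_server  # reused number: appears to span days
            else:
                srv = server_counter
            prev_server = srv

            start_t = t
            audit_rows.append((pid, t, "Login", None, agent, srv))
            n_actions = 1 + int(rng.negative_binomial(
                config.actions_nbinom_n, config.actions_nbinom_p))
            primary = fn_names[int(rng.choice(len(fn_names), p=fn_probs))]
            counts = {n: 0 for n in fn_names}
            prev_label = None
            for _ in range(n_actions):
                if rng.random() < config.p_primary:
                    fn = primary
                else:
                    fn = fn_names[int(rng.choice(len(fn_names), p=fn_probs))]
                choices = [
                    lab for lab in labels_by_fn.get(fn, []) if lab != prev_label
                ]
                if not choices:
                    continue
                label = choices[int(rng.integers(len(choices)))]
                t += _draw_gap(rng, config.within_gap_meanlog,
                               config.within_gap_sdlog, 1,
                               config.threshold_seconds)
                audit_rows.append((pid, t, label, None, None, srv))
                counts[fn] += 1
                prev_label = label
                if (
                    config.mobile_duplicates
                    and mobile
                    and rng.random() < config.p_burst
                ):
                    extra = int(rng.geometric(1.0 / config.burst_mean_length))
                    for _ in range(extra):
                        t += 2
                        audit_rows.append((pid, t, label, None, None, srv))

            idle = False
            if not mobile:
                if config.keepalive_logout and rng.random() < config.p_idle_desktop:
                    idle = True
                    delay = int(rng.integers(config.keepalive_delay_min,
                                             config.keepalive_delay_max + 1))
                    t += delay
                    audit_rows.append((pid, t, "Logout", "Logout", None, srv))
                else:
                    # manual log-out shortly after the last action
                    t += _draw_gap(rng, config.within_gap_meanlog,
                                   config.within_gap_sdlog, 1,
                                   config.threshold_seconds)
                    audit_rows.append((pid, t, "Logout", "Logout", None, srv))

            truth_rows.append(
                {
                    "patient_id": pid,
                    "session_index": k,
                    "start_time": start_t,
                    "device": "mobile" if mobile else "desktop",
                    "has_agent": has_agent,
                    "idle_keepalive": idle,
                    "n_actions": n_actions,
                    **counts,
                }
            )
            t += int(config.threshold_seconds) + 1 + int(round(float(
                rng.lognormal(config.between_gap_meanlog,
                              config.between_gap_sdlog))))

    # -- assemble frames ---------------------------------------------------
    def fmt(seconds: Sequence[int]) -> pd.Series:
        ts = base + pd.to_timedelta(list(seconds), unit="s")
        return pd.Series(ts).dt.strftime("%Y-%m-%d %H:%M:%S")

    if audit_rows:
        pids, times, actions, extendeds, agents, srvs = zip(*audit_rows)
        stamps = base + pd.to_timedelta(list(times), unit="s")
        srv_out = []
        for stamp, srv in zip(stamps, srvs):
            if missing_cut is not None and stamp < missing_cut:
                srv_out.append("Null")
            else:
                srv_out.append(str(srv))
        audit = pd.DataFrame(
            {
                "PAT_MRN_ID": pids,
                "UA_TIME": pd.Series(stamps).dt.strftime("%Y-%m-%d %H:%M:%S"),
                "MYC_UA_TYPE_C": actions,
                "UA_EXTENDED_INFO": [e or "Null" for e in extendeds],
                "UA_SESSION_NUM": srv_out,
                "UA_USER_AGENT": [a or "Null" for a in agents],
            }
        )
    else:
        audit = pd.DataFrame(
            columns=["PAT_MRN_ID", "UA_TIME", "MYC_UA_TYPE_C",
                     "UA_EXTENDED_INFO", "UA_SESSION_NUM", "UA_USER_AGENT"]
        )

    if status_rows:
        s_pids, s_status, s_times, s_method, s_comment = zip(*status_rows)
        status = pd.DataFrame(
            {
                "PAT_MRN_ID": s_pids,
                "MYC_STATUS_HX": s_status,
                "MYC_STATUS_TMSTP": fmt(s_times),
                "MYC_STATUS_MTHD": s_method,
                "MYC_STATUS_CMT": [c or "Null" for c in s_comment],
            }
        )
    else:
        status = pd.DataFrame(
            columns=["PAT_MRN_ID", "MYC_STATUS_HX", "MYC_STATUS_TMSTP",
                     "MYC_STATUS_MTHD", "MYC_STATUS_CMT"]
        )

    truth_sessions = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "session_index", "start_time", "device",
                 "has_agent", "idle_keepalive", "n_actions"] + fn_names,
    )
    if len(truth_sessions):
        truth_sessions["start_time"] = (
            base + pd.to_timedelta(truth_sessions["start_time"], unit="s")
        )
    else:
        truth_sessions["start_time"] = pd.Series(dtype="datetime64[ns]")
    truth_status = pd.DataFrame(
        truth_status_rows,
        columns=["patient_id", "current_status", "activated", "deceased"],
    )
    return SimResult(
        audit=audit,
        status=status,
        truth=GroundTruth(sessions=truth_sessions, status=truth_status),
        config=config,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """How faithfully the pipeline recovered the generator's ground truth."""

    boundary_precision: float
    boundary_recall: float
    device_accuracy: float
    n_device_scored: int
    count_error: int
    count_error_rate: float
    n_true_sessions: int
    n_detected_sessions: int

    def as_dict(self) -> dict:
        return asdict(self)


def score_recovery(
    truth: GroundTruth,
    sessions: Sequence[Session],
    patients: Sequence[PatientMetrics],
) -> RecoveryReport:
    """Score recovered sessions and patient metrics against ground truth.

    Boundaries are matched on (patient, session start time).  Detected
    sessions consisting solely of log-out records are excluded from
    boundary scoring: they are the known fallout of keep-alive log-outs
    landing beyond the inactivity threshold, carry zero duration and are
    filtered by the validity rule downstream.  Device accuracy is scored
    on matched sessions whose true log-in carried a user agent.  The count
    error is the total absolute difference between recovered patient-level
    function counts and the generator's pre-artifact truth.
    """
    truth_key = {}
    for row in truth.sessions.itertuples(index=False):
        truth_key[(row.patient_id, pd.Timestamp(row.start_time))] = row

    detected = []
    for s in sessions:
        if (~s.records["is_logout"].astype(bool)).any():
            detected.append(s)

    matched = [
        s for s in detected if (s.patient_id, s.start_time) in truth_key
    ]
    n_true = len(truth_key)
    precision = len(matched) / len(detected) if detected else 1.0
    recall = len(matched) / n_true if n_true else 1.0

    scored = correct = 0
    for s in matched:
        row = truth_key[(s.patient_id, s.start_time)]
        if row.has_agent:
            scored += 1
            if s.device == row.device:
                correct += 1
    device_accuracy = correct / scored if scored else 1.0

    true_counts = truth.patient_function_counts()
    fn_names = [f.value for f in METRIC_FUNCTIONS]
    obs = {
        p.patient_id: {f.value: c for f, c in p.function_counts.items()}
        for p in patients
    }
    error = 0
    total_true = 0
    all_pids = set(true_counts.index) | set(obs)
    for pid in all_pids:
        t_row = (
            true_counts.loc[pid] if pid in true_counts.index
            else {n: 0 for n in fn_names}
        )
        o_row = obs.get(pid, {n: 0 for n in fn_names})
        for name in fn_names:
            tv = int(t_row[name])
            total_true += tv
            error += abs(int(o_row.get(name, 0)) - tv)
    return RecoveryReport(
        boundary_precision=precision,
        boundary_recall=recall,
        device_accuracy=device_accuracy,
        n_device_scored=scored,
        count_error=error,
        count_error_rate=error / total_true if total_true else 0.0,
        n_true_sessions=n_true,
        n_detected_sessions=len(detected),
    )
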