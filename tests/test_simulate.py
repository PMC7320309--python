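import numpy as np
import pandas as pd
import pytest
from scipy import stats

from portal_sessions import (
    ConfigError,
    SimConfig,
    assign_sessions,
    canonical_sort,
    compute_gaps,
    dedup_actions,
    patient_metrics,
    read_audit_log,
    score_recovery,
    session_metrics,
    simulate_cohort,
    status_table,
    summarize_accounts,
)
from portal_sessions.status import read_status_log


def run_cohort(sim, taxonomy, threshold=1256.0, dedup=True, tmp_path=None):
    """Push a simulated cohort through the analysis pipeline in memory."""
    path = tmp_path / "audit.tsv"
    sim.audit.to_csv(path, sep="\t", index=False)
    log = canonical_sort(read_audit_log(path), taxonomy)
    assert len(log.rejected) == 0
    sessions = assign_sessions(log, threshold, taxonomy)
    if dedup:
        sessions = [dedup_actions(s) for s in sessions]
    sm = [session_metrics(s, taxonomy) for s in sessions]
    return sessions, sm, patient_metrics(sm)


class TestGenerator:
    def test_deterministic_under_seed(self):
        a = simulate_cohort(SimConfig(n_patients=20, seed=9,
                                      keepalive_logout=True,
                                      mobile_duplicates=True))
        b = simulate_cohort(SimConfig(n_patients=20, seed=9,
                                      keepalive_logout=True,
                                      mobile_duplicates=True))
        assert a.audit.to_csv(index=False) == b.audit.to_csv(index=False)
        assert a.status.to_csv(index=False) == b.status.to_csv(index=False)
        assert (
            a.truth.sessions.to_csv(index=False)
            == b.truth.sessions.to_csv(index=False)
        )

    def test_empty_cohort(self):
        sim = simulate_cohort(SimConfig(n_patients=0, seed=1))
        assert len(sim.audit) == 0
        assert len(sim.status) == 0
        assert len(sim.truth.sessions) == 0

    def test_invalid_mixture_rejected(self):
        cfg = SimConfig(function_mixture={"Messaging": 0.5, "Visits": 0.2})
        with pytest.raises(ConfigError, match="sum to 1"):
            simulate_cohort(cfg)

    def test_parses_with_zero_rejects(self, taxonomy, tmp_path):
        sim = simulate_cohort(SimConfig(n_patients=10, seed=3,
                                        keepalive_logout=True,
                                        mobile_duplicates=True))
        path = tmp_path / "audit.tsv"
        sim.audit.to_csv(path, sep="\t", index=False)
        log = read_audit_log(path)
        assert len(log) == len(sim.audit)
        assert len(log.rejected) == 0

    def test_keepalive_logout_timing(self):
        """With the artifact on and mobile off, every idle desktop session's
        final log-out lands 1200-1320 s after its last real activity."""
        sim = simulate_cohort(SimConfig(n_patients=50, seed=4, p_mobile=0.0,
                                        keepalive_logout=True))
        audit = sim.audit.copy()
        audit["t"] = pd.to_datetime(audit["UA_TIME"])
        idle = sim.truth.sessions[sim.truth.sessions["idle_keepalive"]]
        assert len(idle) > 0
        for row in idle.itertuples(index=False):
            patient_rows = audit[audit["PAT_MRN_ID"] == row.patient_id]
            in_session = patient_rows[
                (patient_rows["t"] >= row.start_time)
            ].head(row.n_actions + 2)  # login + actions + logout
            assert in_session["MYC_UA_TYPE_C"].iloc[-1] == "Logout"
            delay = (
                in_session["t"].iloc[-1] - in_session["t"].iloc[-2]
            ).total_seconds()
            assert 1200 <= delay <= 1320

    def test_within_gap_distribution_matches_lognormal(self, taxonomy, tmp_path):
        """Two-sided KS-style check of emitted within-session gaps against
        the configured log-normal (continuity-corrected for the whole-second
        quantization; upper tail conditioned on the threshold clamp)."""
        cfg = SimConfig(n_patients=500, seed=6, p_missing_agent=0.0)
        sim = simulate_cohort(cfg)
        path = tmp_path / "audit.tsv"
        sim.audit.to_csv(path, sep="\t", index=False)
        log = canonical_sort(read_audit_log(path), taxonomy)
        obs = compute_gaps(log, taxonomy)
        # within-session gaps: later action neither log-out (manual log-out
        # timing) nor log-in (between-session spacing)
        frame = log.frame
        same = (
            frame["patient_id"].eq(frame["patient_id"].shift())
            .fillna(False).to_numpy()
        )
        later_login = frame.loc[same, "action_type"].eq("Login").to_numpy()
        within = obs.loc[
            ~obs["current_action_is_logout"].to_numpy() & ~later_login,
            "gap_seconds",
        ].to_numpy()
        assert len(within) >= 10_000
        scale = np.exp(cfg.within_gap_meanlog)
        cdf = stats.lognorm(s=cfg.within_gap_sdlog, scale=scale).cdf
        f_cap = cdf(cfg.threshold_seconds)
        xs = np.sort(within)
        ecdf = np.arange(1, len(xs) + 1) / len(xs)
        model = np.minimum(cdf(xs + 0.5) / f_cap, 1.0)
        d = np.max(np.abs(ecdf - model))
        critical = 1.628 / np.sqrt(len(xs))  # alpha = 0.01
        assert d < critical

    def test_multiday_server_ids_do_not_affect_recovery(self, taxonomy, tmp_path):
        cfg = SimConfig(n_patients=40, seed=8, multiday_session_num=0.2,
                        missing_session_num_before="2017-03-01")
        sim = simulate_cohort(cfg)
        sessions, sm, pm = run_cohort(sim, taxonomy, tmp_path=tmp_path)
        report = score_recovery(sim.truth, sessions, pm)
        assert report.boundary_precision == 1.0
        assert report.boundary_recall == 1.0
        assert report.count_error == 0


class TestRecoveryScoring:
    def test_perfect_recovery_with_artifacts_off(self, taxonomy, tmp_path):
        sim = simulate_cohort(SimConfig(n_patients=60, seed=12))
        sessions, sm, pm = run_cohort(sim, taxonomy, tmp_path=tmp_path)
        report = score_recovery(sim.truth, sessions, pm)
        assert report.boundary_precision == 1.0
        assert report.boundary_recall == 1.0
        assert report.device_accuracy == 1.0
        assert report.count_error == 0

    def test_dedup_required_for_exact_counts(self, taxonomy, tmp_path):
        sim = simulate_cohort(SimConfig(n_patients=40, seed=13,
                                        mobile_duplicates=True, p_mobile=1.0,
                                        p_burst=0.5))
        with_dedup = score_recovery(
            sim.truth, *run_cohort(sim, taxonomy, tmp_path=tmp_path)[::2]
        )
        sessions, sm, pm = run_cohort(sim, taxonomy, dedup=False,
                                      tmp_path=tmp_path)
        without = score_recovery(sim.truth, sessions, pm)
        assert with_dedup.count_error == 0
        assert without.count_error > 0


class TestStatusEmission:
    def test_status_mixture_recovered_exactly(self, tmp_path):
        sim = simulate_cohort(SimConfig(n_patients=150, seed=14))
        path = tmp_path / "status.tsv"
        sim.status.to_csv(path, sep="\t", index=False)
        events = read_status_log(path)
        summaries = summarize_accounts(events)
        got = {
            s.patient_id: s.current_status for s in summaries
        }
        for row in sim.truth.status.itertuples(index=False):
            assert got[row.patient_id] == row.current_status
        table = status_table(summaries)
        assert table["n"].sum() == len(sim.truth.status)
        assert table["percent"].sum() == pytest.approx(100.0)

    def test_deceased_truth_matches(self, tmp_path):
        sim = simulate_cohort(SimConfig(n_patients=300, seed=15))
        path = tmp_path / "status.tsv"
        sim.status.to_csv(path, sep="\t", index=False)
        summaries = {
            s.patient_id: s for s in summarize_accounts(read_status_log(path))
        }
        truth = sim.truth.status
        assert truth["deceased"].any()  # cohort large enough to include some
        for row in truth.itertuples(index=False):
            assert summaries[row.patient_id].deceased == row.deceased
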