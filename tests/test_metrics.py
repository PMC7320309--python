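import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from portal_sessions import (
    PortalFunction,
    assign_sessions,
    cohort_summary,
    dedup_actions,
    patient_metrics,
    session_metrics,
    session_metrics_frame,
)
from conftest import make_log

THRESHOLD = 1256.0


def burst_log(taxonomy, n_repeats=5, spacing=2):
    rows = [("p", "2018-01-01 09:00:00", "Login")]
    t0 = np.datetime64("2018-01-01T09:00:10")
    for i in range(n_repeats):
        ts = str(t0 + np.timedelta64(i * spacing, "s")).replace("T", " ")
        rows.append(("p", ts, "Visits", "Get future appt list"))
    return make_log(rows, taxonomy=taxonomy)


class TestDedup:
    def test_mobile_burst_collapses_to_first(self, taxonomy):
        (session,) = assign_sessions(burst_log(taxonomy), THRESHOLD, taxonomy)
        deduped = dedup_actions(session)
        assert deduped.n_actions == 2  # log-in + one Visits action
        assert deduped.duration_seconds == session.duration_seconds

    def test_alternating_records_survive(self, table3_log, taxonomy):
        """Inbox list / message read / inbox list alternation is preserved;
        only the genuinely consecutive identical pair (the two successive
        message-read rows) collapses."""
        sessions = assign_sessions(table3_log, THRESHOLD, taxonomy)
        third = sessions[2]
        sub = third.records.iloc[2:5]  # the alternating messaging triple
        assert sub["extended_info"].tolist() == [
            "Inbox message list", "Message read", "Inbox message list"
        ]
        deduped = dedup_actions(third)
        assert deduped.n_actions == third.n_actions - 1
        kept = deduped.records["extended_info"].tolist()
        assert kept[2:5] == [
            "Inbox message list", "Message read", "Inbox message list"
        ]

    def test_single_record_unchanged(self, taxonomy):
        log = make_log([("p", "2018-01-01 09:00:00", "Visits")], taxonomy=taxonomy)
        (session,) = assign_sessions(log, THRESHOLD, taxonomy)
        assert dedup_actions(session).n_actions == 1

    def test_idempotent(self, taxonomy):
        (session,) = assign_sessions(burst_log(taxonomy), THRESHOLD, taxonomy)
        once = dedup_actions(session)
        twice = dedup_actions(once)
        assert twice.n_actions == once.n_actions

    def test_max_interval_preserves_slow_repeats(self, taxonomy):
        log = burst_log(taxonomy, n_repeats=3, spacing=120)
        (session,) = assign_sessions(log, THRESHOLD, taxonomy)
        assert dedup_actions(session, max_interval=60).n_actions == 4
        assert dedup_actions(session, max_interval=300).n_actions == 2

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_never_increases_counts(self, seed, taxonomy):
        rng = np.random.default_rng(seed)
        labels = ["Visits", "Messaging", "Test results", "Login", "Logout"]
        t = np.datetime64("2018-01-01T09:00:00")
        rows = []
        for _ in range(int(rng.integers(1, 40))):
            t = t + np.timedelta64(int(rng.integers(1, 30)), "s")
            rows.append(
                ("p", str(t).replace("T", " "),
                 labels[int(rng.integers(len(labels)))])
            )
        log = make_log(rows, taxonomy=taxonomy)
        for session in assign_sessions(log, THRESHOLD, taxonomy):
            before = session_metrics(session, taxonomy)
            after = session_metrics(dedup_actions(session), taxonomy)
            for fn in before.function_counts:
                assert after.function_counts[fn] <= before.function_counts[fn]


class TestSessionMetrics:
    def test_excerpt_second_session(self, table3_log, taxonomy):
        sessions = assign_sessions(table3_log, THRESHOLD, taxonomy)
        m = session_metrics(dedup_actions(sessions[1]), taxonomy)
        assert m.function_counts[PortalFunction.MESSAGING] == 1
        assert m.comprehensiveness == 1
        assert m.is_valid  # 754 s

    def test_login_logout_only_session(self, taxonomy):
        log = make_log(
            [("p", "2018-01-01 09:00:00", "Login"),
             ("p", "2018-01-01 09:00:05", "Logout")],
            taxonomy=taxonomy,
        )
        (session,) = assign_sessions(log, THRESHOLD, taxonomy)
        m = session_metrics(session, taxonomy)
        assert all(v == 0 for v in m.function_counts.values())
        assert m.comprehensiveness == 0
        assert not m.is_valid
        assert m.n_miscellaneous == 2

    def test_two_functions_comprehensiveness(self, taxonomy):
        log = make_log(
            [("p", "2018-01-01 09:00:00", "Message center"),
             ("p", "2018-01-01 09:00:30", "Bill payment")],
            taxonomy=taxonomy,
        )
        (session,) = assign_sessions(log, THRESHOLD, taxonomy)
        m = session_metrics(session, taxonomy)
        assert m.comprehensiveness == 2

    def test_unclassified_reported_not_counted(self, taxonomy):
        log = make_log(
            [("p", "2018-01-01 09:00:00", "Message center"),
             ("p", "2018-01-01 09:00:30", "MysteryWidget")],
            taxonomy=taxonomy,
        )
        (session,) = assign_sessions(log, THRESHOLD, taxonomy)
        m = session_metrics(session, taxonomy)
        assert m.n_unclassified == 1
        assert sum(m.function_counts.values()) == 1
        assert m.comprehensiveness == 1


class TestPatientMetrics:
    def _metrics(self, taxonomy, rows):
        log = make_log(rows, taxonomy=taxonomy)
        sessions = assign_sessions(log, THRESHOLD, taxonomy)
        return [session_metrics(dedup_actions(s), taxonomy) for s in sessions]

    def test_union_over_valid_sessions(self, taxonomy):
        sm = self._metrics(
            taxonomy,
            [("p", "2018-01-01 09:00:00", "Message center"),
             ("p", "2018-01-01 09:00:40", "Letters"),
             ("p", "2018-01-02 09:00:00", "Login"),
             ("p", "2018-01-02 09:01:00", "eCheck-in")],
        )
        (pm,) = patient_metrics(sm)
        assert pm.n_sessions_valid == 2
        assert pm.comprehensiveness == 2
        assert pm.is_active
        # conservation: patient counts equal the sum over valid sessions
        for fn in pm.function_counts:
            assert pm.function_counts[fn] == sum(
                m.function_counts[fn] for m in sm if m.is_valid
            )

    def test_one_valid_session_not_active(self, taxonomy):
        sm = self._metrics(
            taxonomy,
            [("p", "2018-01-01 09:00:00", "Message center"),
             ("p", "2018-01-01 09:00:40", "Letters")],
        )
        (pm,) = patient_metrics(sm)
        assert pm.n_sessions_valid == 1
        assert not pm.is_active

    def test_invalid_sessions_excluded_from_counts(self, taxonomy):
        sm = self._metrics(
            taxonomy,
            [("p", "2018-01-01 09:00:00", "Message center"),  # zero duration
             ("p", "2018-01-02 09:00:00", "eCheck-in"),
             ("p", "2018-01-02 09:01:00", "Allergies")],
        )
        (pm,) = patient_metrics(sm)
        assert pm.n_sessions_total == 2
        assert pm.n_sessions_valid == 1
        assert pm.function_counts[PortalFunction.MESSAGING] == 0

    def test_empty_input(self):
        assert patient_metrics([]) == []


class TestCohortSummary:
    def test_multi_function_fraction(self, taxonomy):
        rows = [
            ("a", "2018-01-01 09:00:00", "Message center"),
            ("a", "2018-01-01 09:00:40", "Letters"),
            ("a", "2018-01-02 09:00:00", "eCheck-in"),
            ("a", "2018-01-02 09:00:30", "Allergies"),
            ("b", "2018-01-03 09:00:00", "Bill payment"),
            ("b", "2018-01-03 09:01:00", "Estimates"),
        ]
        log = make_log(rows, taxonomy=taxonomy)
        sm = [
            session_metrics(dedup_actions(s), taxonomy)
            for s in assign_sessions(log, THRESHOLD, taxonomy)
        ]
        pm = patient_metrics(sm)
        summary = cohort_summary(pm, sm)
        # three valid sessions with comprehensiveness {1, 2, 1}
        assert summary["n_sessions_valid"] == 3
        assert summary["fraction_multi_function"] == pytest.approx(1 / 3)
        hist = summary["session_comprehensiveness_hist"]
        assert sum(hist.values()) == summary["n_sessions_valid"]
        assert sum(summary["patient_comprehensiveness_hist"].values()) == len(pm)

    def test_empty_cohort(self):
        summary = cohort_summary([], [])
        assert summary["n_sessions_valid"] == 0
        assert summary["fraction_multi_function"] == 0.0


def test_session_frame_column_order(table3_log, taxonomy):
    sessions = assign_sessions(table3_log, THRESHOLD, taxonomy)
    sm = [session_metrics(dedup_actions(s), taxonomy) for s in sessions]
    frame = session_metrics_frame(sm)
    assert list(frame.columns[:5]) == [
        "session_id", "patient_id", "start_time", "device", "duration_seconds"
    ]
    assert frame["is_valid"].tolist() == [False, True, True]
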