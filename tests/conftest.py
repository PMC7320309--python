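from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from portal_sessions import AuditLog, canonical_sort, load_taxonomy, read_audit_log

# The published worked example: one patient's fortnight of portal activity,
# reproduced as a TSV export (identifiers redacted as in the source).
TABLE3_TSV = "\n".join(
    [
        "PAT_MRN_ID\tUA_TIME\tMYC_UA_TYPE_C\tUA_EXTENDED_INFO\tUA_USER_AGENT\tUA_SESSION_NUM",
        "xxxxx\t2018-09-17 09:20:38\tMessaging\tMedadvice-form\tNull\t561234",
        "xxxxx\t2018-09-19 12:40:38\tMessaging\tMedadvice-form\tNull\t561234",
        "xxxxx\t2018-09-19 12:53:12\tMessaging\tMedadvice-form\tNull\t561234",
        "xxxxx\t2018-09-19 13:47:04\tLogin\tNull\tEpicMyChart-iPhone\t561234",
        "xxxxx\t2018-09-19 13:47:08\tProvider List Widget\tGet-prov-list\tNull\t561234",
        "xxxxx\t2018-09-19 13:48:05\tMessaging\tInbox message list\tNull\t561234",
        "xxxxx\t2018-09-19 13:48:08\tMessaging\tMessage read\tNull\t561234",
        "xxxxx\t2018-09-19 13:48:37\tMessaging\tInbox message list\tNull\t561234",
        "xxxxx\t2018-09-19 13:49:05\tMessaging\tMessage read\tNull\t561234",
        "xxxxx\t2018-09-19 13:49:19\tMessaging\tMessage read\tNull\t561234",
        "xxxxx\t2018-09-19 13:50:07\tVisits\tGet future appt list\tNull\t561234",
        "xxxxx\t2018-09-19 13:50:08\tVisits\tGet past appt list\tNull\t561234",
        "xxxxx\t2018-09-19 13:50:19\tEncounter Details\tPast appt dat: 5xxx\tNull\t561234",
        "xxxxx\t2018-09-19 14:06:00\tLogout\tLogout\tNull\t561234",
    ]
) + "\n"


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def table3_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("table3") / "audit_excerpt.tsv"
    path.write_text(TABLE3_TSV)
    return path


@pytest.fixture()
def table3_log(table3_path, taxonomy) -> AuditLog:
    return canonical_sort(read_audit_log(table3_path), taxonomy)


def make_log(rows, sort=True, taxonomy=None) -> AuditLog:
    """Build an AuditLog from (patient_id, timestamp, action_type[,
    extended_info[, user_agent]]) tuples; timestamps may be strings or
    datetimes."""
    records = []
    for i, row in enumerate(rows):
        pid, ts, action = row[0], row[1], row[2]
        extended = row[3] if len(row) > 3 else None
        agent = row[4] if len(row) > 4 else None
        records.append(
            {
                "patient_id": pid,
                "timestamp": pd.Timestamp(ts),
                "action_type": action,
                "extended_info": extended,
                "server_session": None,
                "user_agent": agent,
            }
        )
    frame = pd.DataFrame(
        records,
        columns=["patient_id", "timestamp", "action_type", "extended_info",
                 "server_session", "user_agent"],
    )
    for col in ("patient_id", "action_type", "extended_info", "server_session",
                "user_agent"):
        frame[col] = frame[col].astype("string")
    frame["input_index"] = np.arange(len(frame), dtype="int64")
    log = AuditLog(frame=frame)
    if sort:
        log = canonical_sort(log, taxonomy)
    return log
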