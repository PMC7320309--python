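# portal-sessions

Session-level and patient-level usage metrics from outpatient-portal
audit logs.

## The problem

Patient portals (e.g. Epic MyChart) log every user action server-side:
one timestamped row per click, tagged with a raw action-type string, a
patient identifier, and sparse metadata (user agent, extended info, a
server-assigned session number). Researchers and quality-improvement
teams want behavioral engagement measures from these logs — how often a
patient uses each portal function, and how broadly — but the raw export
is not analysis-ready:

* the server session number is unreliable (untracked in older data,
  intermittently assigned, occasionally spanning several days);
* idle desktop connections are closed by a server-stamped **keep-alive
  log-out** ~20 minutes after the last real action, inflating apparent
  session durations and spiking the inter-action gap distribution;
* the mobile client re-logs the same action every ~2 seconds while a
  page stays open (**duplicate bursts**), inflating action counts;
* raw action strings are site- and version-specific and must be mapped
  to a stable two-level taxonomy of portal functions.

This package implements the full processing chain from raw delimited
exports to validated metric tables, plus a synthetic-cohort generator
with ground truth so every stage is testable without protected health
information.

## Method

1. **Ingest & canonical order** — normalize the six audit columns
   (`PAT_MRN_ID`, `UA_TIME`, `MYC_UA_TYPE_C`, `UA_EXTENDED_INFO`,
   `UA_SESSION_NUM`, `UA_USER_AGENT`), reject unparseable rows into a
   report, and totally order records by patient and time with log-ins
   first and log-outs last within a second.
2. **Inactivity threshold** — compute the gap `g_i = t_i − t_{i−1}`
   (seconds) between consecutive actions of the same patient. After
   excluding gaps whose later action is a log-out (the keep-alive
   spike), the threshold is the empirical retention quantile
   `T = Q_g(r)` with `r = 0.998` by default; a fixed default
   `T = 1256 s` (~20 min) is available when estimation is skipped.
3. **Sessionization** — a new session starts at a patient's first
   record, at any log-in, after any gap `> T`, and after a log-out.
   Server session numbers are ignored.
4. **Device & duration** — a session is `mobile` if any record carries a
   mobile-client marker (default `EpicMyChart`), `desktop` if a log-in
   carries a marker-free agent, else `unknown`. Effective duration
   excludes log-out records: last minus first non-log-out timestamp.
5. **Taxonomy** — raw action strings map to 44 action labels under 8
   portal functions (Messaging, Visits, My record, Medical tools,
   Billing, Resources, Proxy, Preferences); log-in/log-out/2FA are
   Miscellaneous and never counted. The mapping is a site-editable YAML.
6. **Metrics** — after collapsing consecutive identical records
   (mobile-burst dedup), per-session and per-patient **frequency**
   (count per function) and **comprehensiveness** (number of distinct
   functions, 0–8). Sessions with zero effective duration are invalid;
   patients need ≥ 2 valid sessions to count as active; patient-level
   counts aggregate valid sessions only.
7. **Account status** — per-patient activation time (earliest
   `Activated` event) and current status from the status-history export,
   with a deceased flag matched in the free-text comment.

## Worked example

The repository's test fixture is a 14-row single-patient log excerpt.
Running the pipeline on it:

```bash
portal-sessions run --audit audit_excerpt.tsv --out out/
```

prints the stage log:

```
[taxonomy] 53 rules loaded
[ingest] 14 records accepted, 0 rejected
[canonical_sort] 14 records ordered
[threshold] 13 gaps, threshold 1256 s (fixed)
[sessionize] 3 sessions over 14 records
[dedup] 2 duplicate records removed
[metrics] 2/3 valid sessions, 1/1 active patients
[status] no status file supplied
```

The 14 records split into three sessions: a lone message-drafting
action two days earlier (duration 0 s — invalid), a two-record
messaging session (duration 754 s, which dedup collapses to a single
Messaging action: frequency 1, comprehensiveness 1), and an 11-record
mobile session (log-in agent `EpicMyChart-iPhone`) whose effective
duration is 195 s because the closing log-out, stamped 941 s after the
last real action, is excluded.

`out/sessions.tsv` and `out/patients.tsv` hold the metric tables, with
one count column per portal function plus comprehensiveness and
validity flags.

## Synthetic cohorts

```bash
portal-sessions simulate --out-dir sim/ --n-patients 200 --seed 1
portal-sessions run --audit sim/audit.tsv --status sim/status.tsv --out out/
```

emits schema-identical audit and status files with both artifact
classes injected, plus ground-truth tables
(`sim/truth_sessions.tsv`, `sim/truth_status.tsv`);
`portal_sessions.score_recovery` compares pipeline output against them
(boundary precision/recall, device accuracy, count error).

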