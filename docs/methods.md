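# Methods

## Model of portal use

The package treats an outpatient-portal audit log as a per-patient point
process of typed events at one-second resolution. Analysis aggregates
events at four levels: *action type* (one logged user action), *portal
function* (one of eight functional areas grouping action types),
*session* (a coherent, limited, uninterrupted run of one patient's
actions), and *patient* (all of a patient's recorded sessions). Usage is
summarized as **frequency** (accesses per function) and
**comprehensiveness** (distinct functions accessed, 0–8) at the session
and patient levels.

Two assumptions underpin sessionization: (1) the server-assigned session
number is too unreliable to define sessions (it is untracked in older
exports, intermittently assigned, and occasionally spans several days),
so sessions are reconstructed from timing and log-in/log-out structure
alone; and (2) a patient inactive for longer than a threshold `T` has
disengaged, so later activity is a new session.

## Canonical ordering

Records sort by (patient, timestamp); within one patient-second,
log-ins rank first and log-outs last, establishing a logical event
order for co-occurrent rows. Remaining ties break on the record's field
values before input position, so the order is invariant to input
permutation except among fully identical rows — without this, the same
log delivered in a different row order could sessionize differently.

## Threshold estimation

The inter-action gap `g` (seconds between an action and the preceding
action of the same patient) is heavy-tailed and approximately
log-normal in its body, with a spurious spike near 20 minutes caused by
server keep-alive log-outs stamped after idle periods. A gap is
attributed to its *later* action; gaps whose later action is a log-out
are excluded from estimation, which removes the spike
(`gap_density_profile` visualizes this on log-spaced bins).

The threshold is the empirical `r`-quantile of the remaining gaps, with
linear interpolation between order statistics (the convention must be
fixed somewhere; linear interpolation is numpy's default and is what
the sort-based oracle in the test suite reproduces). Defaults:
`r = 0.998`, i.e. 99.8% of non-log-out gaps are preserved intact, and a
fixed fallback `T = 1256 s` for callers that skip estimation. Whether
the retention is the criterion and the threshold its consequence or
vice versa is site policy; the package exposes retention as the control
parameter and the constant as a default, and `estimate_threshold` is
monotone in retention.

Note that the estimate reflects the composition of the gap pool: on
data where between-visit returns are rare or long (as in the synthetic
cohorts below, where revisits always exceed the threshold), the extreme
quantile lands in the between-visit tail rather than at the
within-session scale. On real cohorts, dominated by frequent short
returns, the high quantile sits near the 20-minute scale.

## Sessionization rules

A new session opens at (a) a patient's first record, (b) any log-in,
(c) any gap strictly greater than `T` (a gap exactly equal to `T` does
not split), and (d) the first record after a log-out. Rule (b) is a
deliberate design choice the timing rules alone would not force: an
explicit re-login is treated as a new engagement even after a short
gap. Sessions consisting solely of auxiliary actions (e.g.
log-in/log-out pairs, or a stray keep-alive log-out split off by rule
(c)) are kept at this stage and removed later by the validity filter,
so the record partition stays exact. Session identifiers are
deterministic (`<patient>-S<ordinal>` in time order).

## Device inference and duration

Device evidence comes from log-in metadata. A session is `mobile` when
any record's user agent or extended info contains a configured
substring marker (default `epicmychart`, case-insensitive); `desktop`
when a log-in carries a non-missing agent free of mobile markers (first
such log-in wins); otherwise `unknown`. The marker list is
configuration because deployments differ.

Effective duration is last-minus-first non-log-out timestamp (0 with
fewer than two non-log-out records), computed *before* deduplication.
Excluding log-outs matters: keep-alive log-outs land ~20 minutes after
the last real action and would otherwise make idle desktop sessions
appear 20+ minutes long, bimodalizing the duration distribution.

## Taxonomy and classification

The shipped YAML maps 44 canonical action labels onto the 8 portal
functions, plus Miscellaneous rules flagging log-in, log-out and
two-factor events (used by sessionization, never counted). Raw log
vocabulary is site- and version-specific, so the config additionally
carries a site-editable raw-string section (exact patterns, optional
extended-info refinement with at most one fallback per action pattern,
optional substring matching). Load-time validation rejects configs in
which any record could match two rules. Unmatched records are counted
as Unclassified in the data-quality report — never dropped, never
counted in metrics. The Resources function is expected to carry zero
counts on real exports: its elements link out of the portal and leave
no captured trace.

## Deduplication and metrics

Consecutive runs of records with identical (action type, extended info)
within a session collapse to their first occurrence. The rule is
value-based, not time-based, because the mobile-client artifact is
defined by value identity; an optional `max_interval` cap exists for
sites that want to preserve slow legitimate repeats. Dedup is
idempotent, never increases any count, and leaves durations untouched.
Note the rule also collapses genuine immediate repeats (e.g. two
message-read actions in a row) — indistinguishable from the artifact at
the log level and accepted as the price of correcting it.

Validity filters: `is_valid ⇔ duration > 0` (log-ins that led to no
navigation are discarded from statistics); `is_active ⇔ ≥ 2 valid
sessions`. Patient-level counts sum over valid sessions only, and
patient comprehensiveness is recomputed from the summed counts. The
cohort summary reports totals, per-patient session-count
median/IQR/max, comprehensiveness histograms at both levels, and the
fraction of valid sessions touching more than one function.

## Account status

Status histories reduce per patient to: activation time = earliest
`Activated` event; current status = latest event (ties by input order,
last wins); deceased = any `Inactivated` event whose comment contains a
configured pattern (default `"deceased"` — the exact vendor encoding is
not standardized, so this is pattern configuration). Unknown status
strings are flagged and carried through. Patients with audit activity
but no status history remain in the metrics with status `unknown`.

## Synthetic cohorts and what they show

The generator emits schema-identical audit and status exports with
known ground truth. Default study conditions, chosen once as a
realistic desk-scale cohort: 200 patients; sessions per patient
`1 + NB(1.5, 0.158)` (right-skewed, mean ≈ 9); actions per session
`1 + NB(1, 0.4)` (mean ≈ 2.5); within-session gaps log-normal
(`μ = ln 45`, `σ = 1.1` — median 45 s) rounded to whole seconds and
clamped to `[1, T]`; between-session gaps `T + 1 +` log-normal
(`μ = ln 20000`, `σ = 1.0` — hours to days), so true boundaries are
unambiguous; function mixture dominated by Messaging/My record/Visits
with Resources at zero; sessions mostly single-function (each action
repeats the session's primary function with probability 0.85); 40%
mobile; 5% of log-ins lack a user agent. Artifacts are switches:
keep-alive log-outs stamped uniformly 1210–1310 s after the last action
of idle desktop sessions, and mobile duplicate bursts (geometric
length, mean 3, 2-second spacing). Unreliable server session numbers
(missing before a cutover date; reused across days) are emulated and
must not affect results.

Recovery scoring matches sessions on (patient, start time). Detected
sessions consisting solely of log-out records are excluded from
boundary scoring: they are precisely the fallout of keep-alive log-outs
landing beyond `T`, carry zero duration, and are removed by the
validity filter downstream. Device accuracy is scored on matched
sessions whose true log-in carried an agent; the count error is the
total absolute difference between recovered patient-level function
counts and pre-artifact truth.

What passing recovery does **not** show about real data: the generator
guarantees that no genuine between-session gap falls below the
threshold and that no two *distinct* consecutive actions share an
(action type, extended info) pair, so boundary recovery and count
recovery are exact by construction when the rules are implemented
correctly. Real cohorts violate both in edge cases (rapid returns
without re-login merge into one session; genuine immediate repeats are
collapsed), so these tests validate the algorithm, not the metric's
field accuracy. Real raw vocabulary will also produce Unclassified
records until the taxonomy's raw section is extended for the site.

## Numerical choices and problem sizes

Quantiles: `numpy.quantile` with linear interpolation. Density
profiles: log-spaced bins, sub-second gaps clamped to 1 s, masses sum
to 1 within 1e-9. Timestamps are timezone-naive at one-second
resolution throughout; format `YYYY-MM-DD HH:MM:SS`, configurable. The
generator's emitted gap distribution is checked against the configured
log-normal with a KS-style statistic at α = 0.01, continuity-corrected
for the whole-second quantization and conditioned on the threshold
clamp. The test suite exercises 100,000-gap quantile recovery (within
5% of the closed-form 99.8% quantile across 20 replicates), 1000
random logs against an independently written reference sessionizer,
500 fuzzed logs for the conservation laws, and a 200-patient
end-to-end cohort with both artifacts on — sizes chosen to exercise
the asymptotics the method relies on while keeping the default run
desk-scale.

## Known limitations

* The raw-string section of the default taxonomy covers the vocabulary
  seen in typical exports; site deployment requires extending it.
* Proxy-aware analysis is out of scope: a proxy context switch is an
  ordinary action of its session.
* No timezone or DST handling: a DST fold can produce a negative
  apparent gap, which canonical sorting will reorder rather than flag.
* Patient identifiers are treated as opaque strings; no linkage,
  demographic merging, or anonymization is performed beyond that.
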