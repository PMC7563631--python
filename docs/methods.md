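# Methods

This note documents the models, parameters, and design choices behind the
package, and what its synthetic data can and cannot show.

## Guidance engine

The cognitive aid is modeled as a finite-state machine over a declarative
flow graph (`src/rrest/data/flow_graph.yaml`). Screens are nodes; a node
either lists sequential action buttons (the screen advances only when all
have been tapped), offers mutually exclusive choices (tapping one branches
immediately), identifies the rhythm (branching into the shockable,
nonshockable, or ROSC pathway), or is terminal. The bundled graph is a
functional reconstruction of a PALS checklist aid — initial assessment, CPR
initiation, rhythm identification, vascular access, epinephrine preparation
and administration on deliberately separate screens, reversible causes,
airway management, CPR quality, defibrillation, and post-ROSC care — not a
pixel-level clone of any particular product. Both pathways are tagged and
every node is reachable from the start screen (enforced at load time).

Time is injected: `tick(dt)` advances a simulated clock, and the engine
never reads wall-clock time, so identical inputs give byte-identical logs.
Within a tick, timers fire in deadline order against absolute schedules
(deadlines re-arm by adding the period, not from "now"), which makes the
number of firings over an interval independent of how the interval is
partitioned into ticks. Simultaneous expiries are ordered by priority
rank; the medication alert (rank 1) always precedes the rhythm-check alert
(rank 2), encoding the rule that timer-triggered medication actions take
priority. Rhythm-check firings increment the CPR cycle counter whether or
not the team responds; alerts persist until acknowledged (rhythm selection
and epinephrine administration acknowledge their own alerts).

Key parameters (all configuration, never literals in code):

| parameter | default | unit | rationale |
|---|---|---|---|
| rhythm-check period | 120 | s | guideline 2-minute cycle |
| medication period | 180 (valid 180–300) | s | lower bound of the 3–5 min epinephrine interval |
| medication countdown start | first administration | — | configurable; starting at case start is the alternative |
| epinephrine | 0.01 mg/kg, max 1 mg, 0.1 mg/mL | — | standard 1:10,000 dosing |
| defibrillation | 2 / 4 / 4 J/kg, cap 10 J/kg, 360 J | J | standard escalating schedule |
| metronome band | 100–120 | /min | recommended compression rate |
| maximum weight | 100 | kg | guards against unit errors |

The medication countdown resets at every administration, reflecting an
interval timer rather than a one-shot countdown.

Two engine modes share one code path. Guided mode enforces screen gating,
runs the countdowns, and logs dose prompts (`DOSE_COMPUTED`) on entering a
medication screen. Unguided mode represents a team working from memory:
any action defined in the graph is legal at any time, and no app
bookkeeping events appear. This lets usual-care (control) and app-guided
(intervention) logs flow through identical scoring code; arm labels never
change engine rules, only the agent policy differs.

## Scenario simulator

Team behavior is modeled at the event-log level only — no physiology, no
communication model — because every scored quantity is a function of which
actions occur and when. Latencies are lognormal (median, σ), chosen for
positivity and the right skew of human response times. The delay from
cardiac-arrest recognition to first epinephrine administration is a
dedicated lognormal parameter, since it is the scenario's dominant timing
outcome; the agent administers at the scheduled time (or the earliest
legal moment after it), deferring the epinephrine screens when the dose is
not yet due.

The default scenario is the nonshockable case: asystole in a 10 kg
infant, evolving to an organized rhythm with pulse after four 2-minute
cycles (~8 minutes), 600 s maximum. Rhythm transitions are declarative
rules over cycle count, epinephrine doses, and elapsed time; unknown rule
fields are configuration errors.

Default policies encode the two study arms as generation conditions:
control teams have epinephrine-delay median 165 s (σ 0.3) and deviation
probabilities 1/5 (ratio), 1/5 (dose/dilution), 2/5 (reversible causes);
intervention teams have delay median 254 s (σ 0.3) and reversible-causes
omission 2/11. An `ideal` policy (fixed 3 s taps, σ = 0, earliest legal
epinephrine, no faults) produces the reference perfect log.

Faults are keyed by checklist item id and injectable deterministically
(`forced_faults`) or probabilistically. Each fault maps to a concrete
behavioral change (late recognition, 30:2 ratio, rate 140/min, wrong
dilution, skipped rhythm check, delayed resumption, …). Two asymmetries
are deliberate:

* omission semantics differ by arm — a control team's omitted action is
  simply absent from the log, while a guided team must still clear the
  screen, so the omission appears as a tap annotated `performed: false`
  (never credited by any scoring rule);
* the epinephrine-interval fault is implemented as delayed redosing
  (interval 400 s, producing gaps above the 330 s bound) rather than
  over-frequent dosing, because administration times are quantized by the
  2-minute cycle structure, which can silently stretch a "too frequent"
  interval back into the acceptable band.

Per-team seeds derive from the master seed by a SplitMix64 finalizer over
`master + (index+1)·golden`, truncated to 31 bits.

What the generator does **not** emulate: rhythm misidentification,
team-internal communication, fatigue or learning across the scenario,
partial/low-quality compressions (quality is carried as payload, not
simulated), and correlations between deviations. Passing tests therefore
demonstrate that the pipeline measures what the logs contain — not that
real teams behave like the agents.

## Scoring instruments

The 16-item deviation checklist and the 7-task (0/1/2, capped total 13)
performance rubric ship as YAML data evaluated by a small predicate
language (performed-tap presence with optional windows and payload
constraints, conjunctions, bounded repeat intervals, and follow-up-within
rules). The published instruments' exact wording is not reproduced here;
items are reconstructions — those beyond the deviation categories the
source study names are flagged `reconstructed: true` in the data files.
Timeliness windows (recognition ≤ 60 s of case start; compressions ≤ 60 s
and monitor ≤ 120 s of recognition; first epinephrine ≤ 300 s; redosing
gaps 150–330 s; CPR resumption ≤ 15 s of each rhythm check) are
configuration values in the instrument files.

"Recognition of cardiac arrest" is an explicit logged action (a tap of
`recognize_ca`), never inferred; time to epinephrine is the first
administration tap minus that timestamp, absent when epinephrine was never
given, and an error if ordering is violated.

Scoring edge rules: a rule that references a payload key absent from a
candidate tap raises an error naming the item (instruments and logs must
agree on vocabulary); the repeat-interval rule passes vacuously with fewer
than two administrations; the follow-up rule applies to every
non-organized rhythm check and passes vacuously when there are none.

## Questionnaires

UEQ scale scores are means of polarity-adjusted items under the standard
26-item, six-scale assignment (shipped as data with a per-item polarity
vector; responses are expected pre-oriented, +3 = positive pole).
Cohort summaries use the sample (n−1) SD and the normal-approximation 95%
CI, mean ± 1.96·sd/√n — this convention, with n = 11 respondents,
reproduces the published usability table's intervals to ±0.005, which a
t-quantile CI does not; n = 11 (team leaders) is therefore adopted as the
respondent count. Cronbach α uses the raw coefficient-alpha formula on the
scale's item matrix and is reported as absent (not NaN) when undefined
(zero total variance or fewer than two items/respondents). At sd = 0 the
CI collapses to the mean.

RTLX: ratings must be multiples of 5 in 0–100; overall workload is the
plain average of the six subscales; band boundaries 40 and 60 are both
"moderate" (the band is inclusive).

Synthetic respondents draw from a normal, clipped to the instrument range
and snapped to the grid — at zero SD this reproduces the target mean
exactly; near the range edges clipping biases the mean slightly, which the
generator does not correct.

## Statistics

Exact Mann–Whitney enumerates all C(nx+ny, nx) splits of the mid-rank
vector; the two-sided p sums both tails at least as extreme as the
observed U (tail overlap clamps p to 1, so identical groups give p = 1).
Exact mode is limited to combined n ≤ 20 (≈184k splits); the approximate
mode is the tie-corrected, continuity-corrected normal approximation.
Fisher's two-sided test follows the "as or less probable" enumeration
rule. The categorical test is chosen per variable: Fisher when any
expected cell is below 5, chi-squared (uncorrected) otherwise, with the
test used labeled in the report. Percentages round half-up to integers;
continuous summaries use Tukey hinges (median-inclusive halves), the
documented quartile convention for these small samples. No multiplicity
correction is applied.

## Problem sizes

Default test and acceptance runs use cohorts of 5–16 teams (the pilot
study's arm sizes), 200-team cohorts for latency parameter recovery with a
2000-resample bootstrap of the median, and ≤4000 synthetic questionnaire
respondents; one simulated case generates ~50–100 events. These sizes keep
every check deterministic or tightly seeded while exercising the full
pipeline.

## Known limitations

* The flow graph, checklist items, and rubric tasks are reconstructions;
  absolute scores depend on the bundled windows and items, and comparisons
  against published per-item results beyond the reported deviation
  categories are not meaningful.
* Observed study outcomes that depend on participant data (median
  workload scores, checklist/rubric medians, p-values between real arms)
  are not reproducible from synthetic logs; the simulator uses the
  published medians and rates as generation parameters, no more.
* The engine models one team acting serially; concurrent actions by
  multiple rescuers are serialized by timestamp.
* Inter-rater reliability is out of scope (scoring is deterministic).
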