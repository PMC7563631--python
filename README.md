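# rrest

A headless, testable re-implementation of a checklist-style cognitive aid
for pediatric cardiac arrest (PCA) management, together with the simulation
and assessment machinery needed to study it: scripted resuscitation-team
agents, deviation and performance scoring, usability/workload questionnaire
scoring, and small-sample group comparisons.

It is written for resuscitation-simulation researchers who want to model,
end to end, how a PALS-guided team (or a usual-care team) moves through a
simulated cardiac-arrest scenario, and how that performance is measured.

## What is inside

**Guidance engine** (`rrest.engine`, `rrest.flow`, `rrest.config`) — a
deterministic state machine over a declarative flow graph of guidance
screens. Sequential actions must all be tapped before a screen advances;
alternative choices branch immediately; a rhythm-identification screen
splits the flow into the shockable (VF/pVT — defibrillate at 2, 4, then up
to 10 J/kg, never above 360 J) and nonshockable (asystole/PEA —
epinephrine 0.01 mg/kg of 1:10,000, max 1 mg) pathways, plus a ROSC
pathway. A repeating 2-minute rhythm-check countdown and a 3-minute
medication countdown raise priority-ordered alerts (medication first); CPR
and ROSC overlays are available from every screen; a 100–120/min metronome
helper paces compressions. Every action is appended to an ordered JSONL
event log. All clinical constants are configuration, not code. Time is
injected (simulated clock), so every run is exactly reproducible.

**Scenario simulator** (`rrest.simulator`) — scripted-team agents drive the
engine through a scenario (default: asystole in a 10 kg infant, organized
rhythm returning after four CPR cycles). Agent behavior is governed by an
`AgentPolicy`: lognormal action latencies, a recognition-to-epinephrine
delay, per-deviation omission/error probabilities, and deterministic fault
injection keyed by checklist item. Intervention-arm teams run the engine
guided; control-arm teams run it with prompts disabled, producing logs of
performed actions only. Cohorts derive per-team seeds from one master seed
(SplitMix64). The module also generates synthetic questionnaire responses
on each instrument's grid.

**Performance scoring** (`rrest.scoring`) — a 16-item deviation checklist
(0 per correct/timely critical action, 1 per deviation; total 0–16, higher
= worse adherence), a 0/1/2 clinical-performance rubric (asystole section,
total 0–13), and time to epinephrine (seconds from the logged recognition
of cardiac arrest to first administration). Instruments are YAML data
evaluated by a small declarative predicate language.

**Questionnaire scoring** (`rrest.questionnaires`) — the 26-item User
Experience Questionnaire (six scales on −3..+3; neutral band ±0.8) with
mean, sample SD, normal-approximation 95% CI (mean ± 1.96·sd/√n) and
Cronbach α per scale; and the NASA Raw Task Load Index (mean of six 0–100
subscales rated in 5-point steps; bands <40 low, 40–60 moderate, >60 high).

**Statistics and reporting** (`rrest.stats`) — exact Mann–Whitney U by full
enumeration of rank splits (mid-ranks for ties) for combined n ≤ 20, the
tie-corrected normal approximation otherwise; two-sided Fisher exact test
("as or less probable" rule) or chi-squared per the expected-count rule;
median (Tukey-hinge quartiles) and count (percent, rounded half-up)
summaries rendered as a two-arm comparison table.

## Worked example

Simulate a 5-control / 11-intervention cohort, score every log, and build
the comparison table:

```python
from rrest import generate_cohort, score_cohort, summarize_cohort

logs = generate_cohort(5, 11, seed=42)
table = summarize_cohort(score_cohort(logs))
print(table[["label", "control_summary", "intervention_summary", "p_value", "test"]])
```

```
                                             label           control_summary     intervention_summary  p_value               test
      Incorrect compressions-to-ventilations ratio                    1 (20)                    0 (0) 0.312500             fisher
         Incorrect dose or dilution of epinephrine                    2 (40)                    0 (0) 0.083333             fisher
 Lack of search and treatment of reversible causes                    3 (60)                   4 (36) 0.596154             fisher
                   Deviation checklist total score                   2 (2-3)                  1 (0-2) 0.068223 mann_whitney_exact
Time (seconds) to first epinephrine administration 214.314 (176.535-242.304) 252.45 (199.434-285.015) 0.583333 mann_whitney_exact
                  Clinical performance total score                11 (11-12)               13 (11-13) 0.112637 mann_whitney_exact
```

Categorical rows read "count (percent)" per arm with a Fisher exact p;
continuous rows read "median (lower–upper hinge)" with an exact
Mann–Whitney p. With this seed, one of five control teams used a wrong
compression-to-ventilation ratio (20%), and the app-guided arm reached
epinephrine later (median 252 s vs 214 s) — the simulator's default
policies emulate exactly this trade-off between fewer deviations and slower
first epinephrine.

The same pipeline is available from the shell:

```bash
rrest simulate-cohort --arms 5,11 --seed 42 --out cohort/
rrest score-logs --in cohort/ --out scores.csv
rrest report --scores scores.csv --out report.md
rrest score-questionnaires --instrument ueq --in ueq.csv --out ueq_summary.csv
```

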