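"""Scripted-team discrete-event simulator driving the guidance engine.

Teams are modeled at the event-log level only: what matters for every
scored quantity is which actions happen and when.  An
:class:`AgentPolicy` describes a team's behavior — lognormal action
latencies (positive, right-skewed, like human response times), a dedicated
recognition-to-epinephrine delay, per-fault omission/error probabilities,
and optional deterministically injected faults keyed by deviation-checklist
item id.

Intervention-arm teams run the engine in guided mode (screen gating,
countdown alerts, automatic dose prompts); control-arm teams run it with
prompts disabled, so their logs contain performed clinical actions but no
app bookkeeping events.  In the control arm an omitted action is simply
absent from the log; in the guided arm the screen must still be cleared, so
an omitted action appears as a tap annotated ``performed: false``.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .config import EngineConfig, PatientProfile, default_config
from .engine import start_case
from .eventlog import EventType, LogEntry, export_log, read_log
from .flow import FlowGraph, Rhythm, default_flow_graph
from .items import KNOWN_FAULTS, expand_faults

_M64 = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15


def derive_seed(master: int, index: int) -> int:
    """SplitMix64-style per-team seed derivation from a master seed.

    ``seed_i = finalize(master + (i + 1) * golden_gamma)`` truncated to 31
    bits; distinct indices give independent, reproducible streams.
    """
    z = (master + (index + 1) * _GOLDEN) & _M64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    z = z ^ (z >> 31)
    return z & 0x7FFFFFFF


class SimulatorError(ValueError):
    pass


class LatencySpec(BaseModel):
    """Lognormal latency: value = median * exp(sigma * Z)."""

    median_s: float = Field(gt=0)
    sigma: float = Field(ge=0)

    def draw(self, rng: np.random.Generator) -> float:
        if self.sigma == 0:
            return self.median_s
        return float(self.median_s * math.exp(self.sigma * rng.standard_normal()))


class TransitionRule(BaseModel):
    """Scenario rhythm transition: fires once every listed condition holds."""

    model_config = ConfigDict(extra="forbid")

    rhythm: Rhythm
    after_cycles: Optional[int] = None
    after_epi_doses: Optional[int] = None
    after_s: Optional[float] = None

    @model_validator(mode="after")
    def _has_condition(self) -> "TransitionRule":
        if self.after_cycles is None and self.after_epi_doses is None and self.after_s is None:
            raise ValueError("transition rule needs at least one condition")
        return self

    def matches(self, cycles: int, epi_doses: int, t_s: float) -> bool:
        return (
            (self.after_cycles is None or cycles >= self.after_cycles)
            and (self.after_epi_doses is None or epi_doses >= self.after_epi_doses)
            and (self.after_s is None or t_s >= self.after_s)
        )


class ScenarioSpec(BaseModel):
    """A simulated case: initial rhythm, patient weight, rhythm transitions.

    The default reconstructs a nonshockable (asystole) arrest in a
    ~10 kg infant that evolves to an organized rhythm with pulse after four
    2-minute CPR cycles (roughly eight minutes of resuscitation).
    """

    initial_rhythm: Rhythm = Rhythm.ASYSTOLE
    weight_kg: float = Field(default=10.0, gt=0)
    transition_rules: list[TransitionRule] = Field(
        default_factory=lambda: [
            TransitionRule(rhythm=Rhythm.ORGANIZED_WITH_PULSE, after_cycles=4)
        ]
    )
    max_duration_s: float = Field(default=600.0, gt=0)

    def rhythm_at(self, cycles: int, epi_doses: int, t_s: float, current: Rhythm) -> Rhythm:
        for rule in self.transition_rules:
            if rule.matches(cycles, epi_doses, t_s):
                return rule.rhythm
        return current


class AgentPolicy(BaseModel):
    """Behavioral parameters of a scripted resuscitation team."""

    arm: Literal["control", "intervention"]
    seed: int = 0
    latency_model: dict[str, LatencySpec] = Field(
        default_factory=lambda: {
            "tap": LatencySpec(median_s=4.0, sigma=0.4),
            "ack": LatencySpec(median_s=2.0, sigma=0.3),
        }
    )
    # Delay from cardiac-arrest recognition to first epinephrine
    # administration; the scenario's dominant timing parameter.
    epi_delay: LatencySpec = Field(
        default_factory=lambda: LatencySpec(median_s=60.0, sigma=0.35)
    )
    epi_repeat_interval_s: float = Field(default=180.0, gt=0)
    omission_probs: dict[str, float] = Field(default_factory=dict)
    dose_error_prob: float = Field(default=0.0, ge=0, le=1)
    forced_faults: tuple[str, ...] = ()

    @field_validator("omission_probs")
    @classmethod
    def _probs_valid(cls, v: dict[str, float]) -> dict[str, float]:
        for name, p in v.items():
            if name not in KNOWN_FAULTS:
                raise ValueError(f"unknown fault name {name!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {name!r} outside [0, 1]")
        return v

    @field_validator("forced_faults")
    @classmethod
    def _faults_valid(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        expand_faults(v)
        return v

    @field_validator("latency_model")
    @classmethod
    def _latency_classes(cls, v: dict[str, LatencySpec]) -> dict[str, LatencySpec]:
        missing = {"tap", "ack"} - set(v)
        if missing:
            raise ValueError(f"latency_model missing classes {sorted(missing)}")
        return v

    def resolve_faults(self, rng: np.random.Generator) -> frozenset[str]:
        """Forced faults plus probabilistic ones, expanded to item ids."""
        probs = dict(self.omission_probs)
        if self.dose_error_prob > 0:
            probs["cd08_epinephrine_dose"] = max(
                probs.get("cd08_epinephrine_dose", 0.0), self.dose_error_prob
            )
        active = set(self.forced_faults)
        for name in sorted(probs):
            if rng.random() < probs[name]:
                active.add(name)
        return expand_faults(active)

    # -- canonical policies ------------------------------------------------

    @classmethod
    def ideal(cls, arm: str = "intervention", seed: int = 0) -> "AgentPolicy":
        """Deterministic, error-free team: fixed short latencies, earliest
        legal epinephrine, no omissions."""
        return cls(
            arm=arm,
            seed=seed,
            latency_model={
                "tap": LatencySpec(median_s=3.0, sigma=0.0),
                "ack": LatencySpec(median_s=2.0, sigma=0.0),
            },
            epi_delay=LatencySpec(median_s=1.0, sigma=0.0),
        )

    @classmethod
    def study_control(cls, seed: int = 0) -> "AgentPolicy":
        """Usual-care team emulating the pilot study's control arm: median
        time to epinephrine 165 s; deviation rates 1/5 (ratio), 1/5
        (dose/dilution), 2/5 (reversible causes)."""
        return cls(
            arm="control",
            seed=seed,
            epi_delay=LatencySpec(median_s=165.0, sigma=0.3),
            omission_probs={
                "incorrect_ratio": 0.2,
                "incorrect_dose_or_dilution": 0.2,
                "reversible_causes_omission": 0.4,
            },
        )

    @classmethod
    def study_intervention(cls, seed: int = 0) -> "AgentPolicy":
        """App-guided team emulating the pilot study's intervention arm:
        median time to epinephrine 254 s; reversible-causes omission 2/11."""
        return cls(
            arm="intervention",
            seed=seed,
            epi_delay=LatencySpec(median_s=254.0, sigma=0.3),
            omission_probs={"reversible_causes_omission": 2.0 / 11.0},
        )


class TeamLog(BaseModel):
    """One team's complete, engine-validated event log."""

    team_id: str
    arm: Literal["control", "intervention"]
    log: list[LogEntry]
    ca_recognition_t_s: float

    model_config = ConfigDict(arbitrary_types_allowed=True)

    @model_validator(mode="after")
    def _recognition_unique(self) -> "TeamLog":
        n = sum(
            1
            for e in self.log
            if e.event is EventType.TAP and e.payload.get("button") == "recognize_ca"
        )
        if n != 1:
            raise ValueError(f"log must contain exactly one recognition tap, found {n}")
        return self


def run_scenario(
    spec: ScenarioSpec,
    policy: AgentPolicy,
    graph: Optional[FlowGraph] = None,
    config: Optional[EngineConfig] = None,
    team_id: str = "T01",
) -> TeamLog:
    """Drive the engine through one scripted case; deterministic per seed."""
    graph = graph or default_flow_graph()
    config = config or default_config()
    rng = np.random.default_rng(policy.seed)
    active = policy.resolve_faults(rng)
    guided = policy.arm == "intervention"
    engine = start_case(
        graph, PatientProfile(weight_kg=spec.weight_kg), config, guided=guided
    )
    period = config.rhythm_check_timer.period_s

    def is_navigation(button_id: str) -> bool:
        hits = graph.find_buttons(button_id)
        return bool(hits) and hits[0][1].navigation

    def wait(dt: float) -> None:
        if dt > 0:
            engine.tick(dt)

    def wait_until(t: float) -> None:
        wait(t - engine.elapsed_s)

    def act(
        button: str,
        performed: bool = True,
        payload: Optional[dict] = None,
        latency: str = "tap",
    ) -> float:
        """Perform (or omit) one action; returns the tap time."""
        if not guided and is_navigation(button):
            return engine.elapsed_s  # screen navigation does not exist without the app
        if not performed and not guided:
            return engine.elapsed_s  # omitted action: nothing happens, no time passes
        wait(policy.latency_model[latency].draw(rng))
        pl = dict(payload or {})
        if not performed:
            pl["performed"] = False
        engine.tap(button, pl or None)
        return engine.elapsed_s

    # --- initial assessment ------------------------------------------------
    act("check_responsiveness")
    act("call_help", performed="cd02_call_for_help" not in active)
    if "cd01_timely_recognition" in active:
        wait(70.0)
    t_recog = act("recognize_ca")

    # --- CPR initiation ----------------------------------------------------
    if "cd03_early_compressions" in active:
        wait(75.0)
    rate = 140 if "cd05_compression_rate" in active else 110
    act("start_compressions", payload={"rate_cpm": rate})
    ratio = "30:2" if "cd04_compression_ventilation_ratio" in active else "15:2"
    act("set_cpr_ratio", payload={"ratio": ratio})
    if "cd06_monitor_attached" in active:
        wait_until(t_recog + 130.0)
    act("attach_monitor")

    # --- epinephrine plan --------------------------------------------------
    if "cd10_first_epinephrine_timely" in active:
        first_epi_at = t_recog + 360.0
    else:
        first_epi_at = t_recog + policy.epi_delay.draw(rng)
    # interval fault: redosing delayed well beyond the 3-5 minute window
    repeat_s = (
        400.0 if "cd11_epinephrine_interval" in active else policy.epi_repeat_interval_s
    )

    dose_ok = "cd08_epinephrine_dose" not in active
    dilution = "1:1000" if "cd09_epinephrine_dilution" in active else "1:10000"
    epi_payload = {"dose_correct": dose_ok, "dilution": dilution}

    # --- CPR cycles --------------------------------------------------------
    current = spec.initial_rhythm
    attempt = 0  # rhythm determinations attempted (incl. a skipped one)
    skipped = False
    iv_done = False
    epi_count = 0
    last_epi = 0.0

    while engine.elapsed_s < spec.max_duration_s:
        if attempt > 0:
            mark = period * (math.floor(engine.elapsed_s / period) + 1)
            if mark >= spec.max_duration_s:
                break
            wait_until(mark)
            wait(policy.latency_model["ack"].draw(rng))
        current = spec.rhythm_at(attempt, epi_count, engine.elapsed_s, current)
        if "cd07_rhythm_check_cadence" in active and attempt == 2 and not skipped:
            # team misses one scheduled rhythm check and keeps compressing
            skipped = True
            attempt += 1
            continue
        engine.select_rhythm(current)
        attempt += 1

        if current.is_organized:
            act("reassess_patient")
            act("post_rosc_care")
            break

        if current.is_shockable:
            act("charge_defibrillator")
            act("clear_patient")
            act("deliver_shock")

        if "cd16_prompt_cpr_resumption" in active:
            wait(30.0)
        act("resume_compressions")

        if not iv_done and "cd12_vascular_access" not in active:
            act("obtain_iv_access")
            iv_done = True
        else:
            act("access_present")

        due = first_epi_at if epi_count == 0 else last_epi + repeat_s
        next_mark = period * (math.floor(engine.elapsed_s / period) + 1)
        if due <= next_mark - 10.0:
            act("give_epinephrine")
            act("prepare_epinephrine", payload=dict(epi_payload))
            wait_until(due)
            engine.tap("administer_epinephrine", dict(epi_payload))
            last_epi = engine.elapsed_s
            epi_count += 1
            act("flush_line")
        else:
            act("defer_epinephrine")

        act("review_reversible_causes", performed="cd13_reversible_causes_search" not in active)
        act("give_fluid_bolus", performed="cd14_hypovolemia_treatment" not in active)
        act("maintain_bvm", performed="cd15_airway_management" not in active)
        act("reassess_cpr_quality")

    engine.end_case()
    return TeamLog(
        team_id=team_id,
        arm=policy.arm,
        log=engine.log,
        ca_recognition_t_s=t_recog,
    )


def generate_cohort(
    n_control: int,
    n_intervention: int,
    spec: Optional[ScenarioSpec] = None,
    control_policy: Optional[AgentPolicy] = None,
    intervention_policy: Optional[AgentPolicy] = None,
    seed: int = 0,
    control_faults: Optional[dict[int, tuple[str, ...]]] = None,
    intervention_faults: Optional[dict[int, tuple[str, ...]]] = None,
    graph: Optional[FlowGraph] = None,
    config: Optional[EngineConfig] = None,
) -> list[TeamLog]:
    """Simulate a two-arm cohort; per-team seeds derive from the master seed.

    ``*_faults`` maps a 0-based team index within its arm to fault names
    injected deterministically into that team (on top of the policy's
    probabilistic faults)."""
    if n_control < 0 or n_intervention < 0:
        raise SimulatorError("cohort sizes must be nonnegative")
    spec = spec or ScenarioSpec()
    control_policy = control_policy or AgentPolicy.study_control()
    intervention_policy = intervention_policy or AgentPolicy.study_intervention()
    graph = graph or default_flow_graph()
    config = config or default_config()

    logs: list[TeamLog] = []
    stream = 0
    for arm, n, base, faults, prefix in (
        ("control", n_control, control_policy, control_faults or {}, "C"),
        ("intervention", n_intervention, intervention_policy, intervention_faults or {}, "I"),
    ):
        for i in range(n):
            extra = tuple(faults.get(i, ()))
            policy = base.model_copy(
                update={
                    "seed": derive_seed(seed, stream),
                    "forced_faults": tuple(base.forced_faults) + extra,
                }
            )
            logs.append(
                run_scenario(
                    spec, policy, graph=graph, config=config,
                    team_id=f"{prefix}{i + 1:02d}",
                )
            )
            stream += 1
    return logs


def write_cohort(logs: list[TeamLog], outdir: str | Path) -> Path:
    """Write one JSONL log per team plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["team_id", "arm", "ca_recognition_t_s", "log_file"])
        for tl in logs:
            fname = f"{tl.team_id}.jsonl"
            export_log(tl.log, outdir / fname)
            writer.writerow([tl.team_id, tl.arm, f"{tl.ca_recognition_t_s:.6f}", fname])
    return outdir


def read_cohort(indir: str | Path) -> list[TeamLog]:
    indir = Path(indir)
    logs: list[TeamLog] = []
    with open(indir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            logs.append(
                TeamLog(
                    team_id=row["team_id"],
                    arm=row["arm"],
                    log=read_log(indir / row["log_file"]),
                    ca_recognition_t_s=float(row["ca_recognition_t_s"]),
                )
            )
    return logs


# --- synthetic questionnaire respondents -----------------------------------

UEQ_RANGE = (-3, 3)
RTLX_RANGE = (0, 100)
RTLX_SUBSCALES = ("mental", "physical", "temporal", "performance", "effort", "frustration")


def _grid_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, step: float, size: int
) -> np.ndarray:
    """Normal draws clipped to [lo, hi] and snapped to the instrument grid."""
    x = rng.normal(mean, sd, size=size) if sd > 0 else np.full(size, float(mean))
    x = np.clip(x, lo, hi)
    return np.round(x / step) * step


def generate_questionnaires(
    n: int,
    instrument: str,
    profile: Optional[dict] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic questionnaire responses on the instrument's own grid.

    ``profile`` maps scale/subscale name (or ``"all"``) to
    ``{"mean": m, "sd": s}``.  UEQ items are integers in [-3, 3]; RTLX
    subscales are multiples of 5 in [0, 100].  Deterministic per seed.
    """
    from .questionnaires import default_ueq_scale_map  # local import: avoid cycle

    rng = np.random.default_rng(seed)
    profile = profile or {}

    def params(key: str, default_mean: float, default_sd: float) -> tuple[float, float]:
        entry = profile.get(key, profile.get("all", {}))
        return float(entry.get("mean", default_mean)), float(entry.get("sd", default_sd))

    if instrument.upper() == "UEQ":
        lo, hi = UEQ_RANGE
        scale_map = default_ueq_scale_map()
        item_scale = {i: name for name, idxs in scale_map.scales.items() for i in idxs}
        data = {"respondent_id": [f"R{i + 1:02d}" for i in range(n)]}
        for item in range(1, 27):
            mean, sd = params(item_scale[item], 1.5, 1.0)
            if not lo <= mean <= hi:
                raise SimulatorError(f"UEQ mean {mean} outside [{lo}, {hi}]")
            data[f"item_{item:02d}"] = _grid_truncnorm(rng, mean, sd, lo, hi, 1, n).astype(int)
        return pd.DataFrame(data)

    if instrument.upper() == "RTLX":
        lo, hi = RTLX_RANGE
        data = {"respondent_id": [f"R{i + 1:02d}" for i in range(n)]}
        for sub in RTLX_SUBSCALES:
            mean, sd = params(sub, 65.0, 12.0)
            if not lo <= mean <= hi:
                raise SimulatorError(f"RTLX mean {mean} outside [{lo}, {hi}]")
            data[sub] = _grid_truncnorm(rng, mean, sd, lo, hi, 5, n).astype(int)
        return pd.DataFrame(data)

    raise SimulatorError(f"unknown instrument {instrument!r}")
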