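"""Deterministic guidance engine for pediatric cardiac-arrest management.

The engine walks a declarative :class:`~rrest.flow.FlowGraph` under an
injected simulated clock.  It enforces the checklist semantics (a screen
advances only once its sequential actions are tapped; alternative choices
branch immediately), runs the repeating rhythm-check and medication
countdowns with priority-ordered alerts, computes weight-based doses and
escalating defibrillation energies, and appends every action to an ordered
event log.

Two modes:

* ``guided=True`` — the full cognitive aid: screen gating, countdown
  alerts, automatic dose prompts.
* ``guided=False`` — prompts disabled.  Taps represent actions a team
  performs from memory: any action defined in the graph is legal at any
  time, there is no screen gating and no timer alert.  Used to produce
  usual-care (control) logs that score through the same pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

from .config import (
    MEDICATION_TIMER,
    RHYTHM_CHECK_TIMER,
    DoseSpec,
    EnergySchedule,
    EngineConfig,
    PatientProfile,
)
from .eventlog import EventType, LogEntry
from .flow import ActionButton, ButtonLayout, FlowGraph, FlowNode, Rhythm

_EPS = 1e-9


class EngineError(ValueError):
    """Raised for illegal operations (bad tap, bad tick, invariant breach)."""


@dataclass(order=True)
class Alert:
    priority_rank: int
    seq: int
    name: str = field(compare=False)
    raised_at_s: float = field(compare=False)


@dataclass
class _Timer:
    spec_name: str
    period_s: int
    priority_rank: int
    repeating: bool
    deadline_s: Optional[float] = None  # absolute; None = disarmed

    def remaining(self, now_s: float) -> Optional[float]:
        if self.deadline_s is None:
            return None
        return max(0.0, self.deadline_s - now_s)


def compute_dose(profile: PatientProfile, spec: DoseSpec) -> dict[str, float]:
    """Weight-based dose: mass capped at the maximum total, volume from the
    configured concentration."""
    mass_mg = min(profile.weight_kg * spec.per_kg, spec.max_total)
    return {"mass_mg": mass_mg, "volume_ml": mass_mg / spec.concentration}


def defib_energy(
    shock_number: int, profile: PatientProfile, schedule: EnergySchedule
) -> float:
    """Escalating shock energy in joules, clamped to the per-kg and absolute caps."""
    if shock_number < 1:
        raise EngineError(f"shock_number must be >= 1, got {shock_number}")
    if shock_number == 1:
        per_kg = schedule.first_j_per_kg
    elif shock_number == 2:
        per_kg = schedule.second_j_per_kg
    else:
        per_kg = schedule.subsequent_j_per_kg
    energy = per_kg * profile.weight_kg
    return min(energy, schedule.cap_j_per_kg * profile.weight_kg, schedule.absolute_cap_j)


def metronome_beats(
    rate_bpm: int, duration_s: float, bounds: tuple[int, int] = (100, 120)
) -> list[float]:
    """Evenly spaced compression-metronome beat times over [0, duration].

    ``floor(duration * rate / 60) + 1`` beats including t = 0; the rate must
    lie within the recommended compression-rate band.
    """
    lo, hi = bounds
    if not lo <= rate_bpm <= hi:
        raise EngineError(f"metronome rate {rate_bpm} outside {lo}-{hi}/minute")
    if duration_s < 0:
        raise EngineError("duration must be nonnegative")
    n = int(math.floor(duration_s * rate_bpm / 60.0 + _EPS)) + 1
    return [i * 60.0 / rate_bpm for i in range(n)]


class Engine:
    """Live case state plus the operations that mutate it.

    All operations log what they do and are deterministic: an identical
    (graph, profile, config, op sequence) yields an identical final state
    and log.
    """

    def __init__(
        self,
        graph: FlowGraph,
        profile: PatientProfile,
        config: Optional[EngineConfig] = None,
        guided: bool = True,
    ):
        config = config or EngineConfig()
        if profile.weight_kg > config.max_weight_kg:
            raise EngineError(
                f"weight {profile.weight_kg} kg exceeds configured maximum "
                f"{config.max_weight_kg} kg"
            )
        self.graph = graph
        self.profile = profile
        self.config = config
        self.guided = guided

        self.node_id: str = graph.start_node
        self.elapsed_s: float = 0.0
        self.cycle_count: int = 0
        self.epi_dose_count: int = 0
        self.shock_count: int = 0
        self.overlay: Optional[str] = None
        self.pending_alerts: list[Alert] = []
        self.log: list[LogEntry] = []
        self.ended: bool = False
        self._tapped: set[str] = set()
        self._alert_seq: int = 0
        self._timers: dict[str, _Timer] = {}

        if guided:
            rc = config.rhythm_check_timer
            self._timers[RHYTHM_CHECK_TIMER] = _Timer(
                rc.name, rc.period_s, rc.priority_rank, rc.repeating, float(rc.period_s)
            )
            med = config.medication_timer
            deadline = (
                float(med.period_s)
                if config.medication_timer_start == "case_start"
                else None
            )
            self._timers[MEDICATION_TIMER] = _Timer(
                med.name, med.period_s, med.priority_rank, med.repeating, deadline
            )
        self._log(EventType.CASE_START, {"weight_kg": profile.weight_kg, "guided": guided})
        self._enter_node(graph.start_node, log_entry_hooks=guided)

    # -- helpers -----------------------------------------------------------

    @property
    def total_counter_s(self) -> float:
        """The top-bar total case counter."""
        return self.elapsed_s

    @property
    def node(self) -> FlowNode:
        return self.graph.nodes[self.node_id]

    def timers_remaining(self) -> dict[str, Optional[float]]:
        return {name: t.remaining(self.elapsed_s) for name, t in self._timers.items()}

    def _log(self, event: EventType, payload: dict[str, Any]) -> None:
        self.log.append(LogEntry(t_s=self.elapsed_s, event=event, payload=payload))

    def _enter_node(self, node_id: str, log_entry_hooks: bool = True) -> None:
        self.node_id = node_id
        self._tapped = set()
        node = self.graph.nodes[node_id]
        if log_entry_hooks and self.guided and node.compute_dose_for:
            drug = node.compute_dose_for
            spec = self.config.doses.get(drug)
            if spec is None:
                raise EngineError(f"node {node_id!r} requires dose config for {drug!r}")
            dose = compute_dose(self.profile, spec)
            self._log(
                EventType.DOSE_COMPUTED,
                {
                    "drug": drug,
                    "mass_mg": round(dose["mass_mg"], spec.round_to),
                    "volume_ml": round(dose["volume_ml"], spec.round_to),
                    "dilution": spec.dilution_label,
                    "weight_kg": self.profile.weight_kg,
                },
            )

    def _ack_alert(self, name: str) -> None:
        self.pending_alerts = [a for a in self.pending_alerts if a.name != name]

    # -- operations --------------------------------------------------------

    def tick(self, dt_s: float) -> None:
        """Advance the simulated clock, firing any expiring timers in time
        order.  Simultaneous expiries raise alerts in priority order
        (medication before rhythm check)."""
        if dt_s <= 0:
            raise EngineError(f"dt_s must be positive, got {dt_s}")
        end = self.elapsed_s + dt_s
        while True:
            armed = [t for t in self._timers.values() if t.deadline_s is not None]
            due = [t for t in armed if t.deadline_s <= end + _EPS]
            if not due:
                break
            fire_at = min(t.deadline_s for t in due)
            batch = sorted(
                (t for t in due if abs(t.deadline_s - fire_at) <= _EPS),
                key=lambda t: t.priority_rank,
            )
            self.elapsed_s = max(self.elapsed_s, fire_at)
            for timer in batch:
                self._log(EventType.TIMER_FIRED, {"timer": timer.spec_name})
                self._alert_seq += 1
                alert = Alert(
                    priority_rank=timer.priority_rank,
                    seq=self._alert_seq,
                    name=timer.spec_name,
                    raised_at_s=self.elapsed_s,
                )
                self.pending_alerts.append(alert)
                self._log(
                    EventType.ALERT_RAISED,
                    {"alert": timer.spec_name, "priority_rank": timer.priority_rank},
                )
                if timer.spec_name == RHYTHM_CHECK_TIMER:
                    self.cycle_count += 1
                if timer.repeating:
                    timer.deadline_s += timer.period_s
                else:
                    timer.deadline_s = None
            self.pending_alerts.sort()
        self.elapsed_s = end

    def tap(self, button_id: str, payload: Optional[dict[str, Any]] = None) -> None:
        """Tap a button on the current screen (guided) or perform any action
        defined in the graph (unguided)."""
        if self.guided:
            node = self.node
            btn = node.button(button_id)
            if btn is None:
                raise EngineError(
                    f"button {button_id!r} is not visible on node {self.node_id!r}"
                )
            if btn.layout is ButtonLayout.SEQUENTIAL and button_id in self._tapped:
                raise EngineError(f"button {button_id!r} already tapped on this screen")
        else:
            hits = self.graph.find_buttons(button_id)
            if not hits:
                raise EngineError(f"unknown action {button_id!r}")
            btn = hits[0][1]
        entry_payload = {"button": button_id, "node": self.node_id}
        if payload:
            entry_payload.update(payload)
        self._log(EventType.TAP, entry_payload)
        self._apply_effect(btn)
        if not self.guided:
            return
        node = self.node
        if btn.layout is ButtonLayout.ALTERNATIVE:
            self._enter_node(node.choices[button_id])
        else:
            self._tapped.add(button_id)
            seq_ids = {
                b.id for b in node.buttons if b.layout is ButtonLayout.SEQUENTIAL
            }
            if seq_ids <= self._tapped and node.next:
                self._enter_node(node.next)

    def _apply_effect(self, btn: ActionButton) -> None:
        if btn.effect == "epi_administered":
            self.epi_dose_count += 1
            med = self._timers.get(MEDICATION_TIMER)
            if med is not None:
                # countdown (re)starts from each administration
                med.deadline_s = self.elapsed_s + med.period_s
            self._ack_alert(MEDICATION_TIMER)
        elif btn.effect == "shock_delivered":
            self.shock_count += 1

    def select_rhythm(self, rhythm: Rhythm) -> None:
        """Record the identified rhythm and branch into its pathway."""
        rhythm = Rhythm(rhythm)
        if self.guided and not self.node.rhythm_choice:
            raise EngineError(
                f"rhythm selection is not available on node {self.node_id!r}"
            )
        self._ack_alert(RHYTHM_CHECK_TIMER)
        self._log(EventType.RHYTHM_SELECTED, {"rhythm": rhythm.value})
        if rhythm.is_organized:
            self._log(EventType.ROSC_DECLARED, {})
        elif rhythm.is_shockable:
            energy = defib_energy(self.shock_count + 1, self.profile, self.config.energy)
            self._log(
                EventType.SHOCK_ADVISED,
                {"shock_number": self.shock_count + 1, "energy_j": round(energy, 1)},
            )
        if self.guided:
            self._enter_node(self.node.rhythm_edges[rhythm.pathway])

    def acknowledge_alert(self, name: str) -> None:
        self._ack_alert(name)

    def open_overlay(self, which: str) -> None:
        """Open the CPR or ROSC overlay; available from every screen and
        independent of node state and timers."""
        if which not in ("CPR", "ROSC"):
            raise EngineError(f"unknown overlay {which!r}")
        self.overlay = which
        self._log(EventType.OVERLAY_OPENED, {"overlay": which})

    def close_overlay(self) -> None:
        if self.overlay is None:
            self._log(EventType.OVERLAY_CLOSED, {"ignored": True})
            return
        self._log(EventType.OVERLAY_CLOSED, {"overlay": self.overlay})
        self.overlay = None

    def end_case(self) -> None:
        if not self.ended:
            self.ended = True
            self._log(EventType.CASE_END, {})

    def state_summary(self) -> dict[str, Any]:
        """Hashable-ish snapshot used by determinism checks."""
        return {
            "node_id": self.node_id,
            "elapsed_s": self.elapsed_s,
            "cycle_count": self.cycle_count,
            "epi_dose_count": self.epi_dose_count,
            "shock_count": self.shock_count,
            "overlay": self.overlay,
            "pending_alerts": [(a.priority_rank, a.seq, a.name) for a in self.pending_alerts],
            "timers": self.timers_remaining(),
            "log_len": len(self.log),
        }


def start_case(
    graph: FlowGraph,
    profile: PatientProfile,
    config: Optional[EngineConfig] = None,
    guided: bool = True,
) -> Engine:
    """Begin a case: state at the start node, rhythm-check countdown armed,
    CASE_START logged."""
    return Engine(graph, profile, config=config, guided=guided)
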