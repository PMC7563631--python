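import pytest
from pydantic import ValidationError

from rrest.config import EngineConfig, PatientProfile, TimerSpec
from rrest.engine import (
    Engine,
    EngineError,
    compute_dose,
    defib_energy,
    metronome_beats,
    start_case,
)
from rrest.eventlog import EventType
from rrest.flow import Rhythm


def _fresh(graph, config, weight=10.0, guided=True):
    return start_case(graph, PatientProfile(weight_kg=weight), config, guided=guided)


class TestStartCase:
    def test_initial_state(self, graph, config):
        eng = _fresh(graph, config)
        assert eng.node_id == graph.start_node
        assert eng.elapsed_s == 0.0
        assert eng.timers_remaining()["rhythm_check"] == 120
        assert [e.event for e in eng.log] == [EventType.CASE_START]

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError):
            PatientProfile(weight_kg=0)

    def test_weight_above_configured_max_rejected(self, graph, config):
        with pytest.raises(EngineError, match="exceeds"):
            _fresh(graph, config, weight=250.0)


class TestTap:
    def test_sequential_gating(self, graph, config):
        eng = _fresh(graph, config)
        eng.tap("check_responsiveness")
        eng.tap("call_help")
        assert eng.node_id == "initial_assessment"
        eng.tap("recognize_ca")
        assert eng.node_id == "start_cpr"

    def test_invisible_button_rejected_without_logging(self, graph, config):
        eng = _fresh(graph, config)
        n = len(eng.log)
        with pytest.raises(EngineError, match="resume_compressions"):
            eng.tap("resume_compressions")
        assert len(eng.log) == n
        assert eng.node_id == graph.start_node

    def test_double_tap_rejected(self, graph, config):
        eng = _fresh(graph, config)
        eng.tap("check_responsiveness")
        with pytest.raises(EngineError, match="already tapped"):
            eng.tap("check_responsiveness")


def _to_rhythm_node(eng):
    for b in ("check_responsiveness", "call_help", "recognize_ca",
              "start_compressions", "set_cpr_ratio", "attach_monitor"):
        eng.tap(b)
    assert eng.node_id == "rhythm_check"


class TestRhythmSelection:
    def test_nonshockable_branch(self, graph, config):
        eng = _fresh(graph, config)
        _to_rhythm_node(eng)
        eng.select_rhythm(Rhythm.ASYSTOLE)
        assert graph.pathway_tags[eng.node_id] in ("nonshockable", "shared")
        assert eng.log[-1].event is EventType.RHYTHM_SELECTED

    def test_shockable_branch_advises_shock(self, graph, config):
        eng = _fresh(graph, config)
        _to_rhythm_node(eng)
        eng.select_rhythm(Rhythm.VF)
        assert graph.pathway_tags[eng.node_id] == "shockable"
        advised = [e for e in eng.log if e.event is EventType.SHOCK_ADVISED]
        assert advised and advised[0].payload["energy_j"] == pytest.approx(20.0)

    def test_organized_rhythm_declares_rosc(self, graph, config):
        eng = _fresh(graph, config)
        _to_rhythm_node(eng)
        eng.select_rhythm(Rhythm.ORGANIZED_WITH_PULSE)
        assert any(e.event is EventType.ROSC_DECLARED for e in eng.log)
        assert eng.node_id == "rosc"

    def test_selection_outside_rhythm_node_rejected(self, graph, config):
        eng = _fresh(graph, config)
        with pytest.raises(EngineError, match="not available"):
            eng.select_rhythm(Rhythm.ASYSTOLE)


class TestTick:
    def test_rhythm_alert_fires_and_rearms(self, graph, config):
        eng = _fresh(graph, config)
        eng.tick(120)
        assert [a.name for a in eng.pending_alerts] == ["rhythm_check"]
        assert eng.timers_remaining()["rhythm_check"] == pytest.approx(120)
        assert eng.cycle_count == 1

    def test_small_tick_no_alert(self, graph, config):
        eng = _fresh(graph, config)
        eng.tick(1)
        assert not eng.pending_alerts
        assert eng.timers_remaining()["rhythm_check"] == pytest.approx(119)

    def test_nonpositive_dt_rejected(self, graph, config):
        eng = _fresh(graph, config)
        with pytest.raises(EngineError):
            eng.tick(0)

    def test_simultaneous_expiry_medication_first(self, graph):
        cfg = EngineConfig(
            medication_timer=TimerSpec(
                name="medication", period_s=240, priority_rank=1, repeating=True
            ),
            medication_timer_start="case_start",
        )
        eng = _fresh(graph, cfg)
        eng.tick(240)  # rhythm fires at 120 and 240; medication fires at 240
        names = [a.name for a in eng.pending_alerts]
        assert names[0] == "medication"
        fired_at_240 = [
            e.payload["timer"]
            for e in eng.log
            if e.event is EventType.TIMER_FIRED and e.t_s == 240
        ]
        assert fired_at_240 == ["medication", "rhythm_check"]

    def test_multiple_periods_in_one_tick(self, graph, config):
        eng = _fresh(graph, config)
        eng.tick(601)
        fired = [e for e in eng.log if e.event is EventType.TIMER_FIRED]
        assert len(fired) == 5  # floor(601/120)
        assert [e.t_s for e in fired] == [120, 240, 360, 480, 600]


class TestOverlay:
    def test_overlay_openable_from_every_node(self, graph, config):
        for node_id in graph.nodes:
            eng = _fresh(graph, config)
            eng.node_id = node_id
            eng.open_overlay("CPR")
            assert eng.overlay == "CPR"
            assert eng.node_id == node_id

    def test_timers_run_under_overlay(self, graph, config):
        eng = _fresh(graph, config)
        eng.open_overlay("ROSC")
        eng.tick(120)
        assert [a.name for a in eng.pending_alerts] == ["rhythm_check"]

    def test_open_close_restores_state(self, graph, config):
        eng = _fresh(graph, config)
        before = eng.state_summary()
        eng.open_overlay("CPR")
        eng.close_overlay()
        after = eng.state_summary()
        before.pop("log_len"), after.pop("log_len")
        assert before == after

    def test_close_without_open_is_logged_noop(self, graph, config):
        eng = _fresh(graph, config)
        eng.close_overlay()
        assert eng.log[-1].payload == {"ignored": True}


class TestDoseAndEnergy:
    def test_dose_examples(self, config):
        spec = config.doses["epinephrine"]
        d = compute_dose(PatientProfile(weight_kg=10), spec)
        assert d["mass_mg"] == pytest.approx(0.1)
        assert d["volume_ml"] == pytest.approx(1.0)
        assert compute_dose(PatientProfile(weight_kg=23.5), spec)["mass_mg"] == pytest.approx(0.235)

    def test_dose_capped_at_max_total(self, config):
        spec = config.doses["epinephrine"].model_copy(update={"max_total": 1.0})
        d = compute_dose(PatientProfile(weight_kg=200), spec)
        assert d["mass_mg"] == pytest.approx(1.0)

    def test_energy_escalation(self, config):
        p = PatientProfile(weight_kg=10)
        assert defib_energy(1, p, config.energy) == pytest.approx(20)
        assert defib_energy(2, p, config.energy) == pytest.approx(40)
        assert defib_energy(5, p, config.energy) == pytest.approx(40)

    def test_energy_absolute_cap(self, config):
        p = PatientProfile(weight_kg=95)
        for k in (1, 2, 5):
            assert defib_energy(k, p, config.energy) <= 360

    def test_invalid_shock_number(self, config):
        with pytest.raises(EngineError):
            defib_energy(0, PatientProfile(weight_kg=10), config.energy)


class TestMetronome:
    def test_beat_times(self):
        assert metronome_beats(120, 1.0) == pytest.approx([0.0, 0.5, 1.0])
        assert metronome_beats(100, 0.59) == pytest.approx([0.0])

    def test_rate_outside_recommended_band_rejected(self):
        with pytest.raises(EngineError, match="100-120"):
            metronome_beats(90, 10)


def test_identical_scripts_give_identical_state_and_log(graph, config):
    def run():
        eng = _fresh(graph, config)
        _to_rhythm_node(eng)
        eng.select_rhythm(Rhythm.ASYSTOLE)
        eng.tick(37.5)
        eng.tap("resume_compressions")
        eng.open_overlay("CPR")
        eng.tick(100)
        eng.close_overlay()
        return eng

    a, b = run(), run()
    assert a.state_summary() == b.state_summary()
    assert a.log == b.log
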