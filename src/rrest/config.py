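"""Engine configuration: timers, weight-based dosing, defibrillation energy.

All clinical constants (epinephrine mg/kg, dilution, shock J/kg, timer
periods) live in configuration — bundled defaults follow the AHA PALS
guideline values — and every computation reads configuration, never
literals, so a guideline revision never requires a code change.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

RHYTHM_CHECK_TIMER = "rhythm_check"
MEDICATION_TIMER = "medication"


class ConfigError(ValueError):
    """Raised for malformed or invariant-violating configuration."""


class PatientProfile(BaseModel):
    """Patient description used for weight-based calculations.

    ``age_label`` is documentation only; every computation keys on weight.
    """

    weight_kg: float = Field(gt=0)
    age_label: str = ""


class TimerSpec(BaseModel):
    """A countdown timer.  Lower ``priority_rank`` = higher alert priority."""

    name: str
    period_s: int = Field(gt=0)
    priority_rank: int
    repeating: bool = True


class DoseSpec(BaseModel):
    """Weight-based drug dose: mass = min(weight * per_kg, max_total)."""

    drug: str
    per_kg: float = Field(gt=0)  # mg/kg
    max_total: float = Field(gt=0)  # mg
    concentration: float = Field(gt=0)  # mg/mL
    round_to: int = 2  # display decimal places
    dilution_label: str = ""


class EnergySchedule(BaseModel):
    """Escalating defibrillation energy in J/kg, with per-kg and absolute caps."""

    first_j_per_kg: float = 2.0
    second_j_per_kg: float = 4.0
    subsequent_j_per_kg: float = 4.0
    cap_j_per_kg: float = 10.0
    absolute_cap_j: float = 360.0

    @model_validator(mode="after")
    def _ordered(self) -> "EnergySchedule":
        seq = (
            self.first_j_per_kg,
            self.second_j_per_kg,
            self.subsequent_j_per_kg,
            self.cap_j_per_kg,
        )
        if any(a > b for a, b in zip(seq, seq[1:])):
            raise ValueError("energy schedule must satisfy first <= second <= subsequent <= cap")
        return self


class EngineConfig(BaseModel):
    """Full engine configuration (timers + dosing + energy + bounds)."""

    rhythm_check_timer: TimerSpec = TimerSpec(
        name=RHYTHM_CHECK_TIMER, period_s=120, priority_rank=2, repeating=True
    )
    medication_timer: TimerSpec = TimerSpec(
        name=MEDICATION_TIMER, period_s=180, priority_rank=1, repeating=True
    )
    # When the medication countdown starts: at case start, or at the first
    # epinephrine administration (default).
    medication_timer_start: Literal["case_start", "first_administration"] = (
        "first_administration"
    )
    doses: dict[str, DoseSpec] = Field(
        default_factory=lambda: {
            "epinephrine": DoseSpec(
                drug="epinephrine",
                per_kg=0.01,
                max_total=1.0,
                concentration=0.1,
                round_to=2,
                dilution_label="1:10000",
            )
        }
    )
    energy: EnergySchedule = Field(default_factory=EnergySchedule)
    metronome_min_bpm: int = 100
    metronome_max_bpm: int = 120
    max_weight_kg: float = 100.0

    @model_validator(mode="after")
    def _check(self) -> "EngineConfig":
        if not 180 <= self.medication_timer.period_s <= 300:
            raise ValueError("medication timer period must lie in 180-300 s")
        if self.metronome_min_bpm > self.metronome_max_bpm:
            raise ValueError("metronome bounds inverted")
        return self


def load_config(path: str | Path) -> EngineConfig:
    """Load an :class:`EngineConfig` from YAML."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return EngineConfig(**raw)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def default_config() -> EngineConfig:
    text = resources.files("rrest.data").joinpath("engine_config.yaml").read_text()
    return EngineConfig(**(yaml.safe_load(text) or {}))
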