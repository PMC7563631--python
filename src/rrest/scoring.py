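"""Event-log performance scoring: deviation checklist, clinical-performance
rubric, and time to epinephrine.

Instruments are declarative YAML data evaluated against a
:class:`~rrest.simulator.TeamLog` by a small predicate language (see the
bundled instrument files for the rule kinds).  An action tap annotated
``performed: false`` — a prompt that was cleared without the action being
carried out — never satisfies a rule.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .eventlog import EventType, LogEntry
from .simulator import TeamLog


class ScoringError(ValueError):
    pass


class ChecklistItem(BaseModel):
    """One deviation-checklist item: 0 if its rule holds, else 1."""

    id: str
    description_key: str = ""
    reconstructed: bool = True
    rule: dict[str, Any]


class ChecklistResult(BaseModel):
    per_item: dict[str, int]
    total: int

    @model_validator(mode="after")
    def _consistent(self) -> "ChecklistResult":
        if self.total != sum(self.per_item.values()):
            raise ValueError("total must equal the sum of per-item scores")
        if any(v not in (0, 1) for v in self.per_item.values()):
            raise ValueError("item scores must be 0 or 1")
        return self


class CPTTask(BaseModel):
    """One performance-rubric task scored 0 / 1 / max_points."""

    id: str
    description_key: str = ""
    max_points: int = Field(default=2, ge=1, le=2)
    presence: dict[str, Any]
    full: Optional[dict[str, Any]] = None


class CPTResult(BaseModel):
    per_task: dict[str, int]
    total: int

    @model_validator(mode="after")
    def _consistent(self) -> "CPTResult":
        if self.total != sum(self.per_task.values()):
            raise ValueError("total must equal the sum of per-task scores")
        return self


# --- instrument loading -----------------------------------------------------


def load_checklist(path: Optional[str | Path] = None) -> list[ChecklistItem]:
    if path is None:
        text = resources.files("rrest.data").joinpath("cdevplus.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return [ChecklistItem(**item) for item in raw["items"]]


def load_cpt(path: Optional[str | Path] = None) -> list[CPTTask]:
    if path is None:
        text = resources.files("rrest.data").joinpath("cpt_asystole.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return [CPTTask(**task) for task in raw["tasks"]]


# --- predicate evaluation ---------------------------------------------------


def _performed_taps(log: list[LogEntry], buttons: list[str]) -> list[LogEntry]:
    return [
        e
        for e in log
        if e.event is EventType.TAP
        and e.payload.get("button") in buttons
        and e.payload.get("performed", True) is not False
    ]


def _payload_ok(tap: LogEntry, rule: dict, item_id: str) -> bool:
    for key, expected in rule.get("payload_equals", {}).items():
        if key not in tap.payload:
            raise ScoringError(
                f"{item_id}: tap at t={tap.t_s} lacks payload key {key!r}"
            )
        if tap.payload[key] != expected:
            return False
    for key, bounds in rule.get("payload_range", {}).items():
        if key not in tap.payload:
            raise ScoringError(
                f"{item_id}: tap at t={tap.t_s} lacks payload key {key!r}"
            )
        lo, hi = bounds
        if not lo <= tap.payload[key] <= hi:
            return False
    return True


def _window(rule: dict, teamlog: TeamLog) -> tuple[float, float]:
    origin = (
        teamlog.ca_recognition_t_s if rule.get("from") == "recognition" else 0.0
    )
    within = rule.get("within_s")
    return origin, (origin + within) if within is not None else float("inf")


def _eval_rule(rule: dict, teamlog: TeamLog, item_id: str) -> bool:
    kind = rule.get("kind")
    log = teamlog.log

    if kind == "tap":
        lo, hi = _window(rule, teamlog)
        candidates = [
            e for e in _performed_taps(log, rule["buttons"]) if lo <= e.t_s <= hi
        ]
        return any(_payload_ok(e, rule, item_id) for e in candidates)

    if kind == "all":
        return all(_eval_rule(sub, teamlog, item_id) for sub in rule["rules"])

    if kind == "max_interval":
        event = EventType(rule["event"])
        times = [e.t_s for e in log if e.event is event]
        if not times:
            return False
        origin = (
            teamlog.ca_recognition_t_s if rule.get("from") == "recognition" else 0.0
        )
        first_within = rule.get("first_within_s", rule["max_gap_s"])
        if times[0] - origin > first_within:
            return False
        return all(b - a <= rule["max_gap_s"] for a, b in zip(times, times[1:]))

    if kind == "interval_range":
        times = [e.t_s for e in _performed_taps(log, rule["buttons"])]
        gaps = [b - a for a, b in zip(times, times[1:])]
        return all(rule["min_gap_s"] <= g <= rule["max_gap_s"] for g in gaps)

    if kind == "resume_within":
        checks = [
            e.t_s
            for e in log
            if e.event is EventType.RHYTHM_SELECTED
            and e.payload.get("rhythm") != "ORGANIZED_WITH_PULSE"
        ]
        resumes = [e.t_s for e in _performed_taps(log, rule["buttons"])]
        within = rule["within_s"]
        return all(any(t < r <= t + within for r in resumes) for t in checks)

    raise ScoringError(f"{item_id}: unknown rule kind {kind!r}")


# --- scoring operations -----------------------------------------------------


def score_cdevplus(
    teamlog: TeamLog, checklist: Optional[list[ChecklistItem]] = None
) -> ChecklistResult:
    """Score the 16-item deviation checklist: 1 point per deviated item."""
    checklist = checklist if checklist is not None else load_checklist()
    per_item = {
        item.id: 0 if _eval_rule(item.rule, teamlog, item.id) else 1
        for item in checklist
    }
    return ChecklistResult(per_item=per_item, total=sum(per_item.values()))


def score_cpt(teamlog: TeamLog, tasks: Optional[list[CPTTask]] = None) -> CPTResult:
    """Score the performance rubric (0/1/2 per task, asystole section 0-13)."""
    tasks = tasks if tasks is not None else load_cpt()
    per_task: dict[str, int] = {}
    for task in tasks:
        if not _eval_rule(task.presence, teamlog, task.id):
            per_task[task.id] = 0
        elif task.full is None or task.max_points == 1:
            per_task[task.id] = task.max_points if task.full is None else 1
        else:
            per_task[task.id] = (
                task.max_points if _eval_rule(task.full, teamlog, task.id) else 1
            )
    return CPTResult(per_task=per_task, total=sum(per_task.values()))


def time_to_epinephrine(teamlog: TeamLog) -> Optional[float]:
    """Seconds from cardiac-arrest recognition to the first epinephrine
    administration; ``None`` when epinephrine was never given."""
    admins = [
        e.t_s for e in _performed_taps(teamlog.log, ["administer_epinephrine"])
    ]
    if not admins:
        return None
    first = min(admins)
    if first < teamlog.ca_recognition_t_s:
        raise ScoringError(
            f"administration at t={first} precedes recognition at "
            f"t={teamlog.ca_recognition_t_s}"
        )
    return first - teamlog.ca_recognition_t_s


def score_cohort(
    logs: list[TeamLog],
    checklist: Optional[list[ChecklistItem]] = None,
    cpt: Optional[list[CPTTask]] = None,
) -> pd.DataFrame:
    """Score every team; one row per team.

    Columns: per-item indicators (``it_<id>``), checklist total, rubric
    total, time to epinephrine, and the derived study variables (incorrect
    ratio, incorrect dose-or-dilution, reversible causes missed).
    """
    checklist = checklist if checklist is not None else load_checklist()
    cpt = cpt if cpt is not None else load_cpt()
    rows = []
    for tl in logs:
        cres = score_cdevplus(tl, checklist)
        pres = score_cpt(tl, cpt)
        row: dict[str, Any] = {"team_id": tl.team_id, "arm": tl.arm}
        row.update({f"it_{k}": v for k, v in cres.per_item.items()})
        row["cdev_total"] = cres.total
        row["cpt_total"] = pres.total
        row["time_to_epi_s"] = time_to_epinephrine(tl)
        row["ratio_incorrect"] = cres.per_item["cd04_compression_ventilation_ratio"]
        row["dose_or_dilution_incorrect"] = max(
            cres.per_item["cd08_epinephrine_dose"],
            cres.per_item["cd09_epinephrine_dilution"],
        )
        row["reversible_causes_missed"] = max(
            cres.per_item["cd13_reversible_causes_search"],
            cres.per_item["cd14_hypovolemia_treatment"],
        )
        rows.append(row)
    return pd.DataFrame(rows)
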