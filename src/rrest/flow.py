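"""Declarative flow graph for the resuscitation guidance screens.

The guidance content is data, not code: a graph of screens ("nodes"), each
carrying action buttons (tapped sequentially) or mutually exclusive choice
buttons, plus a dedicated rhythm-identification node that branches into the
shockable / nonshockable / ROSC pathways.  The bundled default graph is a
reconstruction of a PALS-style checklist app for pediatric cardiac arrest.
"""

from __future__ import annotations

import enum
from collections import deque
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class FlowGraphError(ValueError):
    """Raised when a flow-graph file is malformed or violates graph invariants."""


class Rhythm(str, enum.Enum):
    """Cardiac rhythm classes the team can identify on the monitor."""

    ASYSTOLE = "ASYSTOLE"
    PEA = "PEA"
    VF = "VF"
    PVT = "PVT"
    ORGANIZED_WITH_PULSE = "ORGANIZED_WITH_PULSE"

    @property
    def is_shockable(self) -> bool:
        return self in (Rhythm.VF, Rhythm.PVT)

    @property
    def is_organized(self) -> bool:
        return self is Rhythm.ORGANIZED_WITH_PULSE

    @property
    def pathway(self) -> str:
        """Pathway key used by rhythm-choice nodes: shockable/nonshockable/rosc."""
        if self.is_organized:
            return "rosc"
        return "shockable" if self.is_shockable else "nonshockable"


class ButtonLayout(str, enum.Enum):
    SEQUENTIAL = "SEQUENTIAL"
    ALTERNATIVE = "ALTERNATIVE"


class ButtonKind(str, enum.Enum):
    ACTION = "ACTION"
    CHOICE = "CHOICE"


class ActionButton(BaseModel):
    """One tappable button on a screen.

    ``effect`` marks buttons with engine-level side effects (dose counting,
    shock counting, cardiac-arrest recognition).  ``navigation`` marks pure
    screen-navigation choices that do not correspond to a clinical action;
    unguided (no-app) logs omit them.
    """

    id: str
    label_key: str = ""
    layout: ButtonLayout = ButtonLayout.SEQUENTIAL
    kind: ButtonKind = ButtonKind.ACTION
    effect: Optional[str] = None  # ca_recognized | epi_administered | shock_delivered
    navigation: bool = False

    @model_validator(mode="after")
    def _label_default(self) -> "ActionButton":
        if not self.label_key:
            object.__setattr__(self, "label_key", f"btn.{self.id}")
        return self


class AdvanceRule(str, enum.Enum):
    ALL_SEQUENTIAL_TAPPED = "ALL_SEQUENTIAL_TAPPED"
    ONE_CHOICE_SELECTED = "ONE_CHOICE_SELECTED"


class FlowNode(BaseModel):
    """One screen of the guidance flow.

    Exactly one of the following shapes is valid:

    * sequential node — SEQUENTIAL/ACTION buttons, ``advance_rule`` is
      ALL_SEQUENTIAL_TAPPED and ``next`` names the successor;
    * choice node — >=2 ALTERNATIVE/CHOICE buttons, rule ONE_CHOICE_SELECTED,
      ``choices`` maps each button id to a successor;
    * rhythm-choice node — ``rhythm_choice`` true, ``rhythm_edges`` maps the
      three pathway keys to successors;
    * terminal node — no buttons, no successors.
    """

    id: str
    buttons: list[ActionButton] = Field(default_factory=list)
    advance_rule: Optional[AdvanceRule] = None
    next: Optional[str] = None
    choices: dict[str, str] = Field(default_factory=dict)
    rhythm_choice: bool = False
    rhythm_edges: dict[str, str] = Field(default_factory=dict)
    compute_dose_for: Optional[str] = None  # drug key; dose auto-computed on entry

    @model_validator(mode="after")
    def _check_shape(self) -> "FlowNode":
        if self.rhythm_choice:
            missing = {"shockable", "nonshockable", "rosc"} - set(self.rhythm_edges)
            if missing:
                raise ValueError(
                    f"node {self.id!r}: rhythm-choice node missing edges {sorted(missing)}"
                )
            return self
        seq = [b for b in self.buttons if b.layout is ButtonLayout.SEQUENTIAL]
        alt = [b for b in self.buttons if b.layout is ButtonLayout.ALTERNATIVE]
        if seq and alt:
            raise ValueError(f"node {self.id!r}: mixes sequential and alternative buttons")
        if alt:
            if len(alt) < 2:
                raise ValueError(f"node {self.id!r}: alternative set needs >=2 buttons")
            if self.advance_rule is not AdvanceRule.ONE_CHOICE_SELECTED:
                raise ValueError(f"node {self.id!r}: alternative buttons require ONE_CHOICE_SELECTED")
            unrouted = {b.id for b in alt} - set(self.choices)
            if unrouted:
                raise ValueError(f"node {self.id!r}: choice buttons without edges: {sorted(unrouted)}")
        elif seq:
            if self.advance_rule is not AdvanceRule.ALL_SEQUENTIAL_TAPPED:
                raise ValueError(f"node {self.id!r}: sequential buttons require ALL_SEQUENTIAL_TAPPED")
        return self

    @property
    def is_terminal(self) -> bool:
        return not self.buttons and not self.rhythm_choice

    def button(self, button_id: str) -> Optional[ActionButton]:
        for b in self.buttons:
            if b.id == button_id:
                return b
        return None

    def successors(self) -> list[str]:
        out: list[str] = []
        if self.next:
            out.append(self.next)
        out.extend(self.choices.values())
        out.extend(self.rhythm_edges.values())
        return out


class FlowGraph(BaseModel):
    """Validated node/edge model of the full guidance flow."""

    nodes: dict[str, FlowNode]
    start_node: str
    pathway_tags: dict[str, str] = Field(default_factory=dict)  # node id -> tag

    @field_validator("pathway_tags")
    @classmethod
    def _check_tag_values(cls, v: dict[str, str]) -> dict[str, str]:
        bad = {t for t in v.values() if t not in {"shockable", "nonshockable", "shared"}}
        if bad:
            raise ValueError(f"unknown pathway tags: {sorted(bad)}")
        return v

    @model_validator(mode="after")
    def _check_graph(self) -> "FlowGraph":
        if self.start_node not in self.nodes:
            raise ValueError(f"start_node {self.start_node!r} not defined")
        for nid, node in self.nodes.items():
            if node.id != nid:
                raise ValueError(f"node key {nid!r} does not match node id {node.id!r}")
            for target in node.successors():
                if target not in self.nodes:
                    raise ValueError(f"node {nid!r}: edge targets missing node {target!r}")
        unreachable = set(self.nodes) - self.reachable_from_start()
        if unreachable:
            raise ValueError(f"unreachable nodes: {sorted(unreachable)}")
        tags = set(self.pathway_tags.values())
        if len(self.nodes) > 1 and not {"shockable", "nonshockable"} <= tags:
            raise ValueError("both shockable and nonshockable pathway tags must be present")
        return self

    def reachable_from_start(self) -> set[str]:
        seen = {self.start_node}
        queue = deque([self.start_node])
        while queue:
            for target in self.nodes[queue.popleft()].successors():
                if target not in seen:
                    seen.add(target)
                    queue.append(target)
        return seen

    def all_button_ids(self) -> set[str]:
        return {b.id for node in self.nodes.values() for b in node.buttons}

    def find_buttons(self, button_id: str) -> list[tuple[str, ActionButton]]:
        return [
            (node.id, b)
            for node in self.nodes.values()
            for b in node.buttons
            if b.id == button_id
        ]


def _graph_from_mapping(raw: dict) -> FlowGraph:
    if not isinstance(raw, dict):
        raise FlowGraphError("flow graph file must contain a mapping at top level")
    try:
        nodes_raw = raw["nodes"]
        nodes = {}
        for nid, spec in nodes_raw.items():
            spec = dict(spec or {})
            spec.setdefault("id", nid)
            nodes[nid] = FlowNode(**spec)
        return FlowGraph(
            nodes=nodes,
            start_node=raw["start_node"],
            pathway_tags=raw.get("pathway_tags", {}),
        )
    except FlowGraphError:
        raise
    except KeyError as exc:
        raise FlowGraphError(f"flow graph missing required key: {exc}") from exc
    except (ValueError, TypeError) as exc:
        raise FlowGraphError(str(exc)) from exc


def load_flow_graph(path: str | Path) -> FlowGraph:
    """Load and validate a flow graph from a YAML file.

    Raises :class:`FlowGraphError` naming the offending node when the schema
    or a graph invariant (dangling edge, unreachable node, missing pathway
    tag) is violated.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FlowGraphError(f"cannot parse {path}: {exc}") from exc
    return _graph_from_mapping(raw)


def default_flow_graph() -> FlowGraph:
    """The bundled pediatric cardiac-arrest flow (both pathways plus ROSC)."""
    text = resources.files("rrest.data").joinpath("flow_graph.yaml").read_text()
    return _graph_from_mapping(yaml.safe_load(text))
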