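"""Append-only timestamped event log and its JSON Lines serialization.

Every action taken during a case is recorded as a :class:`LogEntry`
(seconds since case start, event type, payload).  Entries are strictly
ordered by time, ties broken by insertion order; the JSONL round trip is
the identity.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable


class EventType(str, enum.Enum):
    CASE_START = "CASE_START"
    TAP = "TAP"
    RHYTHM_SELECTED = "RHYTHM_SELECTED"
    TIMER_FIRED = "TIMER_FIRED"
    ALERT_RAISED = "ALERT_RAISED"
    OVERLAY_OPENED = "OVERLAY_OPENED"
    OVERLAY_CLOSED = "OVERLAY_CLOSED"
    DOSE_COMPUTED = "DOSE_COMPUTED"
    SHOCK_ADVISED = "SHOCK_ADVISED"
    ROSC_DECLARED = "ROSC_DECLARED"
    CASE_END = "CASE_END"


class LogError(ValueError):
    """Raised for malformed log files or ordering violations."""


@dataclass(frozen=True)
class LogEntry:
    t_s: float
    event: EventType
    payload: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"t_s": self.t_s, "event": self.event.value, "payload": self.payload},
            sort_keys=True,
            separators=(",", ":"),
        )

    @classmethod
    def from_json(cls, line: str) -> "LogEntry":
        obj = json.loads(line)
        if not isinstance(obj, dict):
            raise ValueError("record is not an object")
        missing = {"t_s", "event"} - set(obj)
        if missing:
            raise ValueError(f"record missing fields {sorted(missing)}")
        t_s = obj["t_s"]
        if not isinstance(t_s, (int, float)) or isinstance(t_s, bool) or t_s < 0:
            raise ValueError(f"invalid t_s {t_s!r}")
        try:
            event = EventType(obj["event"])
        except ValueError:
            raise ValueError(f"unknown event type {obj['event']!r}") from None
        payload = obj.get("payload", {})
        if not isinstance(payload, dict):
            raise ValueError("payload must be an object")
        return cls(t_s=float(t_s), event=event, payload=payload)


def validate_order(entries: Iterable[LogEntry]) -> None:
    """Check the nondecreasing-time invariant; raise :class:`LogError` otherwise."""
    prev = None
    for i, entry in enumerate(entries):
        if prev is not None and entry.t_s < prev:
            raise LogError(f"entry {i}: timestamp {entry.t_s} precedes {prev}")
        prev = entry.t_s


def export_log(entries: list[LogEntry], path: str | Path) -> Path:
    """Write a log as JSON Lines (one entry per line)."""
    validate_order(entries)
    path = Path(path)
    path.write_text("".join(e.to_json() + "\n" for e in entries))
    return path


def read_log(path: str | Path) -> list[LogEntry]:
    """Read a JSONL log, validating schema and time ordering.

    Errors name the offending 1-based line number.
    """
    entries: list[LogEntry] = []
    prev = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                entry = LogEntry.from_json(line)
            except (json.JSONDecodeError, ValueError) as exc:
                raise LogError(f"line {lineno}: {exc}") from exc
            if prev is not None and entry.t_s < prev:
                raise LogError(
                    f"line {lineno}: timestamp {entry.t_s} precedes previous {prev}"
                )
            prev = entry.t_s
            entries.append(entry)
    return entries
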