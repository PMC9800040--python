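"""Structured conversion log.

Every change the converter makes on its own initiative (degrading an
association to a generic process, repairing a port assignment, attaching an
orphan auxiliary unit) is recorded here rather than silently applied or
fatally raised.  Three severities mirror the usual log taxonomy:

- ``notification`` — a change made to accommodate elements with no direct
  representation in the target palette;
- ``warning`` — something suspect that was repaired or tolerated;
- ``error`` — an element that could not be converted (conversion continues;
  one bad element never aborts a file).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Severity(str, Enum):
    NOTIFICATION = "notification"
    WARNING = "warning"
    ERROR = "error"


class DegradationRule(str, Enum):
    ASSOC_TO_PROCESS = "assoc_to_process"
    DISSOC_TO_PROCESS = "dissoc_to_process"
    UPDOWN_TAG_TO_LEFT = "updown_tag_to_left"
    OTHER = "other"


@dataclass(frozen=True)
class Record:
    severity: Severity
    rule: str
    element: str
    message: str

    def to_dict(self) -> dict:
        return {
            "severity": self.severity.value,
            "rule": self.rule,
            "element": self.element,
            "message": self.message,
        }


@dataclass
class ConversionReport:
    records: list[Record] = field(default_factory=list)
    input_path: Optional[str] = None
    output_path: Optional[str] = None
    elapsed_s: Optional[float] = None

    def add(self, severity: Severity, rule: str, element: str, message: str) -> Record:
        rec = Record(severity, rule, element, message)
        self.records.append(rec)
        return rec

    def notify(self, rule: str, element: str, message: str) -> Record:
        return self.add(Severity.NOTIFICATION, rule, element, message)

    def warn(self, rule: str, element: str, message: str) -> Record:
        return self.add(Severity.WARNING, rule, element, message)

    def error(self, rule: str, element: str, message: str) -> Record:
        return self.add(Severity.ERROR, rule, element, message)

    def degradation(self, rule: DegradationRule, element: str, message: str) -> Record:
        return self.notify(rule.value, element, message)

    @property
    def degradations(self) -> list[Record]:
        rules = {r.value for r in DegradationRule}
        return [r for r in self.records if r.rule in rules]

    def count(self, severity: Severity) -> int:
        return sum(1 for r in self.records if r.severity is severity)

    @property
    def has_errors(self) -> bool:
        return any(r.severity is Severity.ERROR for r in self.records)

    @property
    def has_warnings(self) -> bool:
        return any(r.severity is Severity.WARNING for r in self.records)

    def extend(self, other: "ConversionReport") -> None:
        self.records.extend(other.records)

    def summary(self) -> dict:
        return {
            "notifications": self.count(Severity.NOTIFICATION),
            "warnings": self.count(Severity.WARNING),
            "errors": self.count(Severity.ERROR),
        }

    def to_json_lines(self) -> str:
        """One JSON object per record, preceded by a summary line."""
        head = {
            "summary": self.summary(),
            "input": self.input_path,
            "output": self.output_path,
            "elapsed_s": self.elapsed_s,
        }
        lines = [json.dumps(head)]
        lines.extend(json.dumps(r.to_dict()) for r in self.records)
        return "\n".join(lines) + "\n"
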