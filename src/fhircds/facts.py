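"""The internal fact model the inference engines reason over.

A :class:`Fact` is one patient-linked coded observation: a concept, a value
(quantity, coded value, boolean, or text), a timestamp and a status. Facts
are immutable and hashable so that bundles convert to plain Python sets and
set-level invariants (order independence, dedup) hold by construction.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass

from .terminology import CodedConcept


class FactStatus(str, enum.Enum):
    FINAL = "final"
    PRELIMINARY = "preliminary"
    AMENDED = "amended"
    ENTERED_IN_ERROR = "entered-in-error"


@dataclass(frozen=True)
class Quantity:
    """Numeric value with an opaque unit string (no UCUM conversion)."""

    value: float
    unit: str = ""

    def __post_init__(self):
        object.__setattr__(self, "value", float(self.value))


#: Value union a Fact may carry.
FactValue = Quantity | CodedConcept | bool | str


@dataclass(frozen=True)
class Fact:
    subject_id: str
    concept: CodedConcept
    value: FactValue
    effective_time: dt.datetime
    status: FactStatus = FactStatus.FINAL

    @property
    def is_usable(self) -> bool:
        """Entered-in-error facts never take part in inference."""
        return self.status is not FactStatus.ENTERED_IN_ERROR

    @property
    def numeric_value(self) -> float | None:
        if isinstance(self.value, Quantity):
            return self.value.value
        return None

    @property
    def unit(self) -> str | None:
        if isinstance(self.value, Quantity):
            return self.value.unit
        return None

    def as_dict(self) -> dict:
        """JSON-friendly rendering (used by the ``facts extract`` CLI)."""
        if isinstance(self.value, Quantity):
            value = {"quantity": self.value.value, "unit": self.value.unit}
        elif isinstance(self.value, CodedConcept):
            value = {"coded": self.value.as_dict()}
        elif isinstance(self.value, bool):
            value = {"boolean": self.value}
        else:
            value = {"text": self.value}
        return {
            "subject": self.subject_id,
            "concept": self.concept.as_dict(),
            "value": value,
            "effective_time": self.effective_time.isoformat(),
            "status": self.status.value,
        }
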