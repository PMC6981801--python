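"""Production-rule formalism: definitions, operation rules, aggregation rules,
artifacts, and strong Kleene three-valued logic.

A *Definition* names an atomic domain concept (a nomenclature plus a code).
An *OperationRule* compares a fact matching a Definition against a reference
value or interval. An *AggregateRule* combines operation rules with AND / OR
/ NOT in an IF part and names an *Artifact* — a typed piece of free-text
decision-support output — in its THEN part.

Missing data is first-class: a rule over an absent (or unit-mismatched, or
non-numeric) fact evaluates to UNKNOWN, and UNKNOWN propagates through the
condition tree by the strong Kleene tables. Artifacts fire only on a
definite TRUE — conservative behaviour for clinical use.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from ..facts import Fact
from ..terminology import CodedConcept


class TriState(enum.Enum):
    """Strong Kleene three-valued truth value.

    Ordered FALSE < UNKNOWN < TRUE so that conjunction is ``min`` and
    disjunction is ``max``, which *is* the strong Kleene semantics.
    """

    FALSE = 0
    UNKNOWN = 1
    TRUE = 2

    def __and__(self, other: "TriState") -> "TriState":
        return TriState(min(self.value, other.value))

    def __or__(self, other: "TriState") -> "TriState":
        return TriState(max(self.value, other.value))

    def __invert__(self) -> "TriState":
        return TriState(2 - self.value)

    @classmethod
    def of(cls, b: bool | None) -> "TriState":
        if b is None:
            return cls.UNKNOWN
        return cls.TRUE if b else cls.FALSE


@dataclass(frozen=True)
class Definition:
    """Atomic domain concept: an id plus a coded concept."""

    id: str
    concept: CodedConcept


class Operation(str, enum.Enum):
    GT = "GT"
    GE = "GE"
    LT = "LT"
    LE = "LE"
    EQ = "EQ"
    NE = "NE"
    IN_RANGE = "IN_RANGE"
    EXISTS = "EXISTS"


_NUMERIC_OPS = {Operation.GT, Operation.GE, Operation.LT, Operation.LE, Operation.IN_RANGE}


@dataclass(frozen=True)
class OperationRule:
    """Reference-interval check on the fact matching one Definition.

    ``unit``, when set, must equal the fact's unit string verbatim —
    units are opaque, there is no conversion, and a mismatch makes the
    rule UNKNOWN rather than silently coercing.
    """

    id: str
    definition_id: str
    operation: Operation
    value: object = None  # scalar, or (low, high) for IN_RANGE, or None for EXISTS
    unit: str | None = None
    nomenclature: str = ""
    code: str = ""
    name: str = ""

    def __post_init__(self):
        if self.operation is Operation.IN_RANGE:
            low, high = self.value  # raises if not a pair
            if low > high:
                raise ValueError(f"OperationRule {self.id}: IN_RANGE low > high")
        elif self.operation in _NUMERIC_OPS:
            float(self.value)

    @property
    def is_numeric(self) -> bool:
        return self.operation in _NUMERIC_OPS


# --- condition trees -------------------------------------------------------


class Condition:
    """Base class for AND/OR/NOT trees whose leaves reference OperationRules."""

    def leaves(self) -> list[str]:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class Leaf(Condition):
    op_rule_id: str

    def leaves(self):
        return [self.op_rule_id]

    def to_dict(self):
        return {"op": self.op_rule_id}


@dataclass(frozen=True)
class And(Condition):
    children: tuple[Condition, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND requires at least two children")

    def leaves(self):
        return [l for c in self.children for l in c.leaves()]

    def to_dict(self):
        return {"and": [c.to_dict() for c in self.children]}


@dataclass(frozen=True)
class Or(Condition):
    children: tuple[Condition, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR requires at least two children")

    def leaves(self):
        return [l for c in self.children for l in c.leaves()]

    def to_dict(self):
        return {"or": [c.to_dict() for c in self.children]}


@dataclass(frozen=True)
class Not(Condition):
    child: Condition

    def leaves(self):
        return self.child.leaves()

    def to_dict(self):
        return {"not": self.child.to_dict()}


def condition_from_dict(node: dict) -> Condition:
    """Build a condition tree from the nested ``{"and"/"or"/"not"/"op"}`` dialect."""
    if not isinstance(node, dict) or len(node) != 1:
        raise ValueError(f"malformed condition node: {node!r}")
    key, payload = next(iter(node.items()))
    if key == "op":
        return Leaf(str(payload))
    if key == "and":
        return And(tuple(condition_from_dict(c) for c in payload))
    if key == "or":
        return Or(tuple(condition_from_dict(c) for c in payload))
    if key == "not":
        return Not(condition_from_dict(payload))
    raise ValueError(f"unknown condition operator: {key!r}")


@dataclass(frozen=True)
class AggregateRule:
    """IF-THEN rule: a condition tree over operation rules, concluding an artifact."""

    id: str
    condition: Condition
    artifact_id: str


class ArtifactType(str, enum.Enum):
    """The ten artifact types, in their fixed report-priority order."""

    SCALE = "Scale"
    RISK = "Risk"
    DIAGNOSIS = "Diagnosis"
    DIAGNOSTIC_REPORT = "DiagnosticReport"
    REFERRAL_REQUEST = "ReferralRequest"
    PROCEDURE_REQUEST = "ProcedureRequest"
    DIAGNOSTIC_REQUEST = "DiagnosticRequest"
    DESCRIPTION = "Description"
    RECOMMENDATION = "Recommendation"
    BEHAVIOR_RECOMMENDATION = "BehaviorRecommendation"


#: Deterministic ordering of fired artifacts in reports and cards.
ARTIFACT_PRIORITY = {t: i for i, t in enumerate(ArtifactType)}


@dataclass(frozen=True)
class Artifact:
    id: str
    type: ArtifactType
    text: str = ""
    concept: CodedConcept | None = None
    payload: tuple = ()

    def __post_init__(self):
        if self.type in (ArtifactType.DESCRIPTION, ArtifactType.RECOMMENDATION) and not self.text:
            raise ValueError(f"Artifact {self.id}: {self.type.value} requires non-empty text")


@dataclass
class RuleTrace:
    """Per-aggregate-rule evaluation record: the rule's TriState and its leaves'."""

    rule_id: str
    result: TriState
    leaf_results: dict[str, TriState] = field(default_factory=dict)


@dataclass
class InferenceResult:
    transaction_id: str
    fired_artifacts: list[Artifact]
    trace: list[RuleTrace]
    facts_used: frozenset[Fact]
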