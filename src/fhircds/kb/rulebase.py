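"""Rule knowledge base: the graph of definitions, rules and artifacts.

Referential integrity is the contract: every OperationRule resolves to a
Definition, every aggregate-rule leaf to an OperationRule, every aggregate
rule to an Artifact, no two Definitions share a concept, and ids are unique
per collection. :func:`validate_kb` reports every breach, naming the
offending ids; the engine refuses an invalid knowledge base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..fhir.resources import ValidationReport
from ..rules.model import AggregateRule, Artifact, Definition, OperationRule
from ..terminology import CodedConcept


@dataclass
class RuleKnowledgeBase:
    id: str
    definitions: dict[str, Definition] = field(default_factory=dict)
    operation_rules: dict[str, OperationRule] = field(default_factory=dict)
    aggregate_rules: dict[str, AggregateRule] = field(default_factory=dict)
    artifacts: dict[str, Artifact] = field(default_factory=dict)
    version: int = 1
    metadata: dict = field(default_factory=dict)

    @classmethod
    def build(cls, id, definitions=(), operation_rules=(), aggregate_rules=(),
              artifacts=(), version=1, metadata=None):
        """Construct from iterables, keying each collection by entity id."""
        return cls(
            id=id,
            definitions={d.id: d for d in definitions},
            operation_rules={r.id: r for r in operation_rules},
            aggregate_rules={r.id: r for r in aggregate_rules},
            artifacts={a.id: a for a in artifacts},
            version=version,
            metadata=dict(metadata or {}),
        )

    def definition_by_concept(self, concept: CodedConcept) -> Definition | None:
        for d in self.definitions.values():
            if d.concept == concept:
                return d
        return None

    def merged(self, other: "RuleKnowledgeBase", id: str | None = None) -> "RuleKnowledgeBase":
        """Union of two knowledge bases (collections must not collide)."""
        return RuleKnowledgeBase(
            id=id or self.id,
            definitions={**self.definitions, **other.definitions},
            operation_rules={**self.operation_rules, **other.operation_rules},
            aggregate_rules={**self.aggregate_rules, **other.aggregate_rules},
            artifacts={**self.artifacts, **other.artifacts},
            metadata={**self.metadata, **other.metadata},
        )


def validate_kb(kb: RuleKnowledgeBase) -> ValidationReport:
    """Check all referential-integrity invariants of a knowledge base."""
    report = ValidationReport()

    seen_concepts: dict[CodedConcept, str] = {}
    for d in kb.definitions.values():
        if d.concept in seen_concepts:
            report.error(
                f"definitions.{d.id}",
                f"duplicate concept {d.concept.system}|{d.concept.code} "
                f"also used by definition {seen_concepts[d.concept]}",
            )
        else:
            seen_concepts[d.concept] = d.id

    for r in kb.operation_rules.values():
        if r.definition_id not in kb.definitions:
            report.error(
                f"operation_rules.{r.id}",
                f"references missing definition {r.definition_id}",
            )

    for ag in kb.aggregate_rules.values():
        for leaf in ag.condition.leaves():
            if leaf not in kb.operation_rules:
                report.error(
                    f"aggregate_rules.{ag.id}",
                    f"condition leaf references missing operation rule {leaf}",
                )
        if ag.artifact_id not in kb.artifacts:
            report.error(
                f"aggregate_rules.{ag.id}",
                f"references missing artifact {ag.artifact_id}",
            )

    return report
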