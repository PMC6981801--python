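"""Interpretation layer: clinical facts in, evidence and ranked diagnoses out.

Continuous measurements are discretized through the stratification each
node declares (ordered half-open intervals, boundary to the upper
stratum); coded values map through the node's code-to-state table; boolean
presence facts assert the node's ``present`` state. Facts whose concept no
node carries are reported, never silently dropped.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field

from ..facts import Fact, Quantity
from ..rules.model import Artifact, ArtifactType, InferenceResult
from ..terminology import CodedConcept
from .model import BayesianModel, BayesNode, Evidence, NodeRole, Posterior


@dataclass
class Interpretation:
    evidence: Evidence = field(default_factory=dict)
    unmapped: list[Fact] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def interpret_facts(facts: set[Fact], model: BayesianModel) -> Interpretation:
    """Map facts onto node states via each node's declared stratification.

    A fact matching a node but falling in no declared stratum produces a
    warning and is skipped (the node stays unobserved).
    """
    by_concept: dict[CodedConcept, BayesNode] = {n.concept: n for n in model.nodes}
    out = Interpretation()
    for fact in sorted(facts, key=repr):
        if not fact.is_usable:
            continue
        node = by_concept.get(fact.concept)
        if node is None:
            out.unmapped.append(fact)
            continue
        state = _state_for(fact, node)
        if state is None:
            out.warnings.append(
                f"fact {fact.concept.code}={fact.value!r} matches node {node.id} "
                f"but maps to no declared state; skipped"
            )
            continue
        prior = out.evidence.get(node.id)
        if prior is not None and prior != state:
            out.warnings.append(
                f"node {node.id}: conflicting interpreted states {prior!r} vs {state!r}; "
                f"keeping the first"
            )
            continue
        out.evidence[node.id] = state
    return out


def _state_for(fact: Fact, node: BayesNode) -> str | None:
    value = fact.value
    if isinstance(value, Quantity):
        return node.state_for_value(value.value)
    if isinstance(value, CodedConcept):
        return node.state_for_code(value.code)
    if isinstance(value, bool):
        wanted = "present" if value else "absent"
        return wanted if wanted in node.states else None
    # free-text value: accept a verbatim state name
    return value if value in node.states else None


@dataclass
class RankedDiagnosis:
    node: BayesNode
    probability: float


def rank_diagnoses(
    post: Posterior, model: BayesianModel, transaction_id: str | None = None
) -> tuple[list[RankedDiagnosis], InferenceResult]:
    """Order diagnosis-role nodes by the posterior of their positive state.

    Descending by probability, ties broken by node id; the ordering is
    independent of node declaration order. Also wraps the ranking as an
    InferenceResult of Diagnosis artifacts for the report emitter.
    """
    ranked = sorted(
        (
            RankedDiagnosis(n, post[n.id][n.positive])
            for n in model.nodes_by_role(NodeRole.DIAGNOSIS)
        ),
        key=lambda r: (-r.probability, r.node.id),
    )
    artifacts = [
        Artifact(
            id=f"diagnosis-{r.node.id}",
            type=ArtifactType.DIAGNOSIS,
            text=(
                f"{r.node.concept.display or r.node.id}: "
                f"P({r.node.positive}) = {r.probability:.3f}"
            ),
            concept=r.node.concept,
        )
        for r in ranked
    ]
    result = InferenceResult(
        transaction_id=transaction_id or uuid.uuid4().hex,
        fired_artifacts=artifacts,
        trace=[],
        facts_used=frozenset(),
    )
    return ranked, result
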