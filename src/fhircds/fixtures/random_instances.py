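"""Seed-deterministic random instances for oracle testing.

Random rule knowledge bases (definitions, operation rules, AND/OR/NOT
trees of bounded depth) and random Bayesian networks (topologically
ordered DAGs, at most three parents per node, binary states, normalized
Dirichlet-style CPT rows). The same seed always yields an identical
instance.
"""

from __future__ import annotations

import datetime as dt
import random

from ..bayes.model import (
    BayesianModel,
    BayesNode,
    CptRow,
    ModelValidation,
    NodeRole,
    ValidationStatus,
)
from ..facts import Fact, Quantity
from ..kb.rulebase import RuleKnowledgeBase
from ..rules.model import (
    AggregateRule,
    And,
    Artifact,
    ArtifactType,
    Condition,
    Definition,
    Leaf,
    Not,
    Operation,
    OperationRule,
    Or,
)
from ..terminology import DEMO, SNOMED_CT, CodedConcept

_ROLES = tuple(NodeRole)


def generate_random_bn(n_nodes: int, seed: int) -> BayesianModel:
    """Random binary-state Bayesian network with ≤3 parents per node.

    Node order is topological by construction; CPT rows are drawn from a
    Dirichlet-style procedure (independent positive draws, renormalized),
    so every model passes validation.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = random.Random(seed)
    states = ("absent", "present")
    nodes = []
    for i in range(n_nodes):
        n_parents = rng.randint(0, min(3, i))
        parents = tuple(f"n{j}" for j in sorted(rng.sample(range(i), n_parents)))
        rows = []
        for combo_index in range(2 ** n_parents):
            given = {
                p: states[(combo_index >> k) & 1] for k, p in enumerate(parents)
            }
            a = rng.random() + 1e-3
            b = rng.random() + 1e-3
            rows.append(CptRow.make(given, {"absent": a / (a + b), "present": b / (a + b)}))
        nodes.append(
            BayesNode(
                id=f"n{i}",
                concept=CodedConcept(SNOMED_CT, f"9{seed % 1000:03d}{i:03d}", f"random node {i}"),
                role=_ROLES[i % len(_ROLES)],
                states=states,
                parents=parents,
                cpt=tuple(rows),
            )
        )
    return BayesianModel(
        id=f"random-bn-{seed}-{n_nodes}",
        nodes=nodes,
        validation=_accepted_validation(),
        metadata={"illustrative": True},
    )


def _accepted_validation() -> ModelValidation:
    return ModelValidation(
        status=ValidationStatus.ACCEPTED,
        signoffs=["fixture-expert-1", "fixture-expert-2"],
    )


def _random_tree(rng: random.Random, op_ids: list[str], depth: int) -> Condition:
    if depth <= 0 or rng.random() < 0.3:
        return Leaf(rng.choice(op_ids))
    kind = rng.choice(["and", "or", "not"])
    if kind == "not":
        return Not(_random_tree(rng, op_ids, depth - 1))
    n_children = rng.randint(2, 3)
    children = tuple(_random_tree(rng, op_ids, depth - 1) for _ in range(n_children))
    return And(children) if kind == "and" else Or(children)


def generate_random_rule_kb(
    n_ops: int, depth: int, seed: int, n_aggregates: int | None = None
) -> RuleKnowledgeBase:
    """Random knowledge base: ``n_ops`` operation rules over distinct demo
    concepts and random condition trees of bounded depth, each concluding
    its own Description artifact."""
    if n_ops < 1:
        raise ValueError("n_ops must be >= 1")
    if depth > 4:
        raise ValueError("depth must be <= 4")
    rng = random.Random(seed)
    definitions = [
        Definition(f"d{i}", CodedConcept(DEMO, f"rc-{seed}-{i}", f"random concept {i}"))
        for i in range(n_ops)
    ]
    numeric_ops = [Operation.GT, Operation.GE, Operation.LT, Operation.LE]
    op_rules = []
    for i in range(n_ops):
        op = rng.choice(numeric_ops + [Operation.IN_RANGE, Operation.EXISTS])
        if op is Operation.IN_RANGE:
            low = round(rng.uniform(0, 5), 2)
            value = (low, round(low + rng.uniform(0.5, 5), 2))
        elif op is Operation.EXISTS:
            value = None
        else:
            value = round(rng.uniform(0, 10), 2)
        op_rules.append(
            OperationRule(id=f"op{i}", definition_id=f"d{i}", operation=op, value=value, unit="")
        )
    if n_aggregates is None:
        n_aggregates = max(1, min(8, n_ops // 2))
    op_ids = [r.id for r in op_rules]
    artifacts = [
        Artifact(f"a{k}", ArtifactType.DESCRIPTION, f"random conclusion {k}")
        for k in range(n_aggregates)
    ]
    ag_rules = [
        AggregateRule(f"ag{k}", _random_tree(rng, op_ids, depth), f"a{k}")
        for k in range(n_aggregates)
    ]
    return RuleKnowledgeBase.build(
        id=f"random-kb-{seed}",
        definitions=definitions,
        operation_rules=op_rules,
        aggregate_rules=ag_rules,
        artifacts=artifacts,
        metadata={"illustrative": True},
    )


def generate_random_facts(
    kb: RuleKnowledgeBase, seed: int, p_present: float = 0.7
) -> set[Fact]:
    """Random fact set for a (random) knowledge base: each definition's
    concept is observed with probability ``p_present``, with a uniform
    numeric value — leaving the rest UNKNOWN exercises the three-valued
    path."""
    rng = random.Random(seed)
    base = dt.datetime(2024, 3, 1, 12, 0, tzinfo=dt.timezone.utc)
    facts: set[Fact] = set()
    for i, d in enumerate(sorted(kb.definitions.values(), key=lambda d: d.id)):
        if rng.random() < p_present:
            facts.add(
                Fact(
                    subject_id="random-patient",
                    concept=d.concept,
                    value=Quantity(round(rng.uniform(0, 12), 3), ""),
                    effective_time=base + dt.timedelta(minutes=i),
                )
            )
    return facts
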