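"""Expert-authored Bayesian diagnostic networks over coded nodes.

A model is a DAG whose nodes represent diagnoses, risk factors, symptoms,
objective signs, and laboratory/instrumental findings. Each node carries a
disease-specific stratification (its ordered discrete states), a
conditional probability table with one row per combination of parent
states, and the coded concept tying it to incoming facts.

CPTs are stored per-row with explicit parent-state labels — the format an
expert authors and reviews — rather than as flat arrays; the inference
module compiles them to dense tables.

Models also track the expert-validation workflow: a model is *accepted*
(deployable for production inference) only after at least two distinct
experts have signed off.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field

import networkx as nx

from ..fhir.resources import ValidationReport
from ..terminology import LOINC, SNOMED_CT, CodedConcept

#: Tolerance for CPT row normalization.
ROW_SUM_TOL = 1e-9


class NodeRole(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    RISK_FACTOR = "risk_factor"
    SYMPTOM = "symptom"
    OBJECTIVE_SIGN = "objective_sign"
    LAB_OR_INSTRUMENTAL = "lab_or_instrumental"


class ValidationStatus(str, enum.Enum):
    PROTOTYPE = "prototype"
    STRUCTURE_VALIDATED = "structure_validated"
    PROBABILITIES_SET = "probabilities_set"
    EXPERT_VALIDATED = "expert_validated"
    ACCEPTED = "accepted"


@dataclass(frozen=True)
class Stratum:
    """Half-open interval [low, high) mapping a numeric value to a state.

    ``None`` bounds are unbounded; a boundary value belongs to the upper
    stratum.
    """

    state: str
    low: float | None = None
    high: float | None = None

    def contains(self, value: float) -> bool:
        lo = -math.inf if self.low is None else self.low
        hi = math.inf if self.high is None else self.high
        return lo <= value < hi


@dataclass(frozen=True)
class CptRow:
    """One conditional distribution row, keyed by explicit parent states."""

    given: tuple[tuple[str, str], ...]  # ((parent_id, state), ...) in parent order
    probabilities: tuple[tuple[str, float], ...]  # ((state, p), ...) in state order

    @classmethod
    def make(cls, given: dict[str, str], probabilities: dict[str, float]) -> "CptRow":
        return cls(
            given=tuple(given.items()),
            probabilities=tuple((s, float(p)) for s, p in probabilities.items()),
        )

    @property
    def given_dict(self) -> dict[str, str]:
        return dict(self.given)

    @property
    def prob_dict(self) -> dict[str, float]:
        return dict(self.probabilities)


@dataclass(frozen=True)
class BayesNode:
    id: str
    concept: CodedConcept
    role: NodeRole
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()
    cpt: tuple[CptRow, ...] = ()
    strata: tuple[Stratum, ...] = ()
    state_codes: tuple[tuple[str, str], ...] = ()  # coded-value code -> state
    positive_state: str | None = None

    def __post_init__(self):
        if len(self.states) < 2:
            raise ValueError(f"node {self.id}: needs at least two states")

    @property
    def positive(self) -> str:
        """State whose probability is reported when ranking diagnoses."""
        if self.positive_state:
            return self.positive_state
        return "present" if "present" in self.states else self.states[0]

    def state_for_value(self, value: float) -> str | None:
        for s in self.strata:
            if s.contains(value):
                return s.state
        return None

    def state_for_code(self, code: str) -> str | None:
        return dict(self.state_codes).get(code)


@dataclass
class ModelValidation:
    status: ValidationStatus = ValidationStatus.PROTOTYPE
    signoffs: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return (
            self.status is ValidationStatus.ACCEPTED
            and len(set(self.signoffs)) >= 2
        )


@dataclass
class BayesianModel:
    id: str
    nodes: list[BayesNode]
    validation: ModelValidation = field(default_factory=ModelValidation)
    version: int = 1
    metadata: dict = field(default_factory=dict)

    def node(self, node_id: str) -> BayesNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def nodes_by_role(self, role: NodeRole) -> list[BayesNode]:
        return [n for n in self.nodes if n.role is role]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        for n in self.nodes:
            for p in n.parents:
                g.add_edge(p, n.id)
        return g

    def topological_order(self) -> list[str]:
        order = list(nx.topological_sort(self.graph()))
        # stable: prefer declaration order among independent nodes
        declared = {nid: i for i, nid in enumerate(self.node_ids)}
        return sorted(order, key=lambda nid: declared[nid]) if _is_topo(self, order) else order


def _is_topo(model: BayesianModel, order) -> bool:
    # declaration order is itself topological for well-authored files
    pos = {nid: i for i, nid in enumerate(model.node_ids)}
    return all(pos[p] < pos[n.id] for n in model.nodes for p in n.parents)


#: Evidence: observed state per node id, at most one state per node.
Evidence = dict[str, str]

#: Posterior: per queried node, a distribution over its states.
Posterior = dict[str, dict[str, float]]


def validate_model(model: BayesianModel) -> ValidationReport:
    """Structural and probabilistic validation of a Bayesian model.

    Errors: duplicate node ids, dangling parents, directed cycles, wrong
    CPT row count, rows not summing to 1 (within 1e-9), entries outside
    [0, 1], rows conditioning on undeclared parents or states. Warnings:
    concepts coded outside LOINC / SNOMED CT, and missing two-expert
    consensus (reported, since only production deployment requires it).
    """
    report = ValidationReport()
    ids = [n.id for n in model.nodes]
    seen = set()
    for nid in ids:
        if nid in seen:
            report.error(f"nodes.{nid}", "duplicate node id")
        seen.add(nid)
    by_id = {n.id: n for n in model.nodes}

    for n in model.nodes:
        for p in n.parents:
            if p not in by_id:
                report.error(f"nodes.{n.id}.parents", f"dangling parent {p}")

    g = model.graph()
    try:
        cycle = nx.find_cycle(g)
        report.error("nodes", "directed cycle: " + " -> ".join(e[0] for e in cycle))
    except nx.NetworkXNoCycle:
        pass

    for n in model.nodes:
        _validate_cpt(n, by_id, report)
        if n.concept.system not in (LOINC, SNOMED_CT):
            report.warning(
                f"nodes.{n.id}.concept",
                f"concept system {n.concept.system} is not LOINC or SNOMED CT",
            )

    if not model.validation.accepted:
        report.warning(
            "validation",
            f"model is not accepted for production: status={model.validation.status.value}, "
            f"distinct signoffs={len(set(model.validation.signoffs))} (two required)",
        )
    return report


def _validate_cpt(n: BayesNode, by_id: dict, report: ValidationReport) -> None:
    expected_rows = 1
    for p in n.parents:
        if p in by_id:
            expected_rows *= len(by_id[p].states)
    if len(n.cpt) != expected_rows:
        report.error(
            f"nodes.{n.id}.cpt",
            f"expected {expected_rows} rows (product of parent state counts), got {len(n.cpt)}",
        )
    seen_rows = set()
    for i, row in enumerate(n.cpt):
        given = row.given_dict
        if set(given) != set(n.parents):
            report.error(
                f"nodes.{n.id}.cpt[{i}]",
                f"row conditions on {sorted(given)} but parents are {sorted(n.parents)}",
            )
            continue
        for p, s in given.items():
            if p in by_id and s not in by_id[p].states:
                report.error(
                    f"nodes.{n.id}.cpt[{i}]", f"unknown state {s!r} for parent {p}"
                )
        key = tuple(given[p] for p in n.parents if p in given)
        if key in seen_rows:
            report.error(f"nodes.{n.id}.cpt[{i}]", "duplicate parent-state row")
        seen_rows.add(key)
        probs = row.prob_dict
        if set(probs) != set(n.states):
            report.error(
                f"nodes.{n.id}.cpt[{i}]",
                f"row states {sorted(probs)} do not match node states {sorted(n.states)}",
            )
            continue
        if any(p < 0 or p > 1 for p in probs.values()):
            report.error(f"nodes.{n.id}.cpt[{i}]", "probability outside [0, 1]")
        total = sum(probs.values())
        if abs(total - 1.0) > ROW_SUM_TOL:
            report.error(
                f"nodes.{n.id}.cpt[{i}]", f"row sums to {total!r}, not 1"
            )


def check_evidence(model: BayesianModel, evidence: Evidence) -> None:
    """Raise ValueError when evidence names unknown nodes or states."""
    for nid, state in evidence.items():
        node = model.node(nid)  # KeyError on unknown node
        if state not in node.states:
            raise ValueError(f"node {nid} has no state {state!r}")
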