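"""Exact inference: joint enumeration (the test oracle) and variable
elimination (the production path).

Expert-authored diagnostic models are small (tens of nodes), so exact
inference is both feasible and preferable to sampling: posteriors are
reproducible and sequential evidence updates provably commute. Variable
elimination with a min-degree ordering is the production algorithm;
:func:`enumerate_joint` materializes the full joint and exists so tests can
condition it by brute force and compare.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from ..errors import ConflictingEvidenceError, InconsistentEvidenceError
from .model import BayesianModel, BayesNode, Evidence, Posterior, check_evidence

#: Upper bound on materialized joint size (entries).
MAX_JOINT_ENTRIES = 2**20


# --- factors ---------------------------------------------------------------


@dataclass
class Factor:
    """Dense factor over a tuple of variables.

    ``table`` has one axis per variable, in ``variables`` order, with axis
    length equal to that node's state count.
    """

    variables: tuple[str, ...]
    table: np.ndarray

    def multiply(self, other: "Factor") -> "Factor":
        variables = self.variables + tuple(v for v in other.variables if v not in self.variables)
        a = _expand(self, variables)
        b = _expand(other, variables)
        return Factor(variables, a * b)

    def marginalize(self, var: str) -> "Factor":
        axis = self.variables.index(var)
        return Factor(
            tuple(v for v in self.variables if v != var),
            self.table.sum(axis=axis),
        )

    def reduce(self, var: str, index: int) -> "Factor":
        axis = self.variables.index(var)
        return Factor(
            tuple(v for v in self.variables if v != var),
            np.take(self.table, index, axis=axis),
        )


def _expand(factor: Factor, variables: tuple[str, ...]) -> np.ndarray:
    """Broadcast a factor's table onto a superset variable ordering."""
    table = factor.table
    # append missing axes, then transpose into target order
    missing = [v for v in variables if v not in factor.variables]
    table = table.reshape(table.shape + (1,) * len(missing))
    current = factor.variables + tuple(missing)
    perm = [current.index(v) for v in variables]
    table = np.transpose(table, perm)
    shape = tuple(
        table.shape[i] if table.shape[i] != 1 or v in factor.variables else 1
        for i, v in enumerate(variables)
    )
    return table.reshape(shape)


def node_factor(node: BayesNode, by_id: dict[str, BayesNode]) -> Factor:
    """Compile a node's per-row CPT into a dense factor over (parents..., node)."""
    parent_states = [by_id[p].states for p in node.parents]
    shape = tuple(len(s) for s in parent_states) + (len(node.states),)
    table = np.zeros(shape)
    rows = {tuple(r.given_dict[p] for p in node.parents): r.prob_dict for r in node.cpt}
    for combo in itertools.product(*parent_states) if node.parents else [()]:
        probs = rows[combo]
        idx = tuple(parent_states[i].index(s) for i, s in enumerate(combo))
        for j, state in enumerate(node.states):
            table[idx + (j,)] = probs[state]
    return Factor(node.parents + (node.id,), table)


# --- joint enumeration (oracle) -------------------------------------------


def enumerate_joint(model: BayesianModel) -> dict[tuple[str, ...], float]:
    """Materialize the full joint distribution by the chain rule.

    Keys are state tuples in node declaration order. Intended for small
    models and for testing; refuses joints above 2**20 entries.
    """
    size = 1
    for n in model.nodes:
        size *= len(n.states)
        if size > MAX_JOINT_ENTRIES:
            raise ValueError(f"joint too large to enumerate (> {MAX_JOINT_ENTRIES} entries)")
    by_id = {n.id: n for n in model.nodes}
    order = model.node_ids
    pos = {nid: i for i, nid in enumerate(order)}
    row_lookup = {
        n.id: {tuple(r.given_dict[p] for p in n.parents): r.prob_dict for r in n.cpt}
        for n in model.nodes
    }
    joint: dict[tuple[str, ...], float] = {}
    for combo in itertools.product(*[n.states for n in model.nodes]):
        p = 1.0
        for n in model.nodes:
            given = tuple(combo[pos[par]] for par in n.parents)
            p *= row_lookup[n.id][given][combo[pos[n.id]]]
        joint[combo] = p
    return joint


# --- variable elimination ---------------------------------------------------


def _min_degree_order(factors: list[Factor], hidden: set[str]) -> list[str]:
    """Greedy min-degree elimination ordering over the factor graph."""
    neighbors: dict[str, set[str]] = {v: set() for v in hidden}
    for f in factors:
        for v in f.variables:
            if v in hidden:
                neighbors[v].update(u for u in f.variables if u != v)
    order = []
    remaining = set(hidden)
    while remaining:
        v = min(remaining, key=lambda u: (len(neighbors[u] & remaining), u))
        order.append(v)
        nbrs = neighbors[v] & remaining - {v}
        for a in nbrs:  # connect v's neighbours (fill-in)
            neighbors[a].update(nbrs - {a})
        remaining.discard(v)
    return order


def _eliminate(factors: list[Factor], order: list[str]) -> Factor:
    factors = list(factors)
    for var in order:
        involved = [f for f in factors if var in f.variables]
        if not involved:
            continue
        product = involved[0]
        for f in involved[1:]:
            product = product.multiply(f)
        product = product.marginalize(var)
        factors = [f for f in factors if var not in f.variables] + [product]
    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    return result


def posterior(
    model: BayesianModel, evidence: Evidence, query: list[str] | None = None
) -> Posterior:
    """Exact marginals P(node | evidence) for every queried node.

    Evidence nodes come back degenerate at their observed state. Evidence
    with probability zero under the model raises
    :class:`InconsistentEvidenceError` rather than returning NaNs.
    """
    check_evidence(model, evidence)
    if query is None:
        query = model.node_ids
    by_id = {n.id: n for n in model.nodes}

    base_factors = []
    for n in model.nodes:
        f = node_factor(n, by_id)
        for ev_node, ev_state in evidence.items():
            if ev_node in f.variables:
                f = f.reduce(ev_node, by_id[ev_node].states.index(ev_state))
        base_factors.append(f)

    out: Posterior = {}
    p_evidence: float | None = None
    for q in query:
        node = by_id[q]
        if q in evidence:
            out[q] = {s: (1.0 if s == evidence[q] else 0.0) for s in node.states}
            continue
        hidden = {v for f in base_factors for v in f.variables} - {q}
        order = _min_degree_order(base_factors, hidden)
        result = _eliminate(base_factors, order)
        # result is over (q,) (evidence already reduced)
        table = _expand(result, (q,)).reshape(len(node.states))
        z = float(table.sum())
        if p_evidence is None:
            p_evidence = z
        if z <= 0.0:
            raise InconsistentEvidenceError(
                f"evidence {evidence} has probability zero under model {model.id}"
            )
        out[q] = {s: float(table[i] / z) for i, s in enumerate(node.states)}

    if p_evidence is None and evidence:
        # all queried nodes were evidence nodes; still verify consistency
        hidden = {v for f in base_factors for v in f.variables}
        order = _min_degree_order(base_factors, hidden)
        z = float(_eliminate(base_factors, order).table)
        if z <= 0.0:
            raise InconsistentEvidenceError(
                f"evidence {evidence} has probability zero under model {model.id}"
            )
    return out


# --- sequential evidence sessions ------------------------------------------


@dataclass
class EvidenceSession:
    """Accumulated findings for one patient encounter.

    Sessions are immutable: each update returns a new session, so sequential
    updates in any order reach the same state as one batch query — exact
    inference guarantees the posteriors agree.
    """

    model: BayesianModel
    evidence: Evidence = field(default_factory=dict)


def update_evidence(
    session: EvidenceSession, node_id: str, state: str
) -> tuple[EvidenceSession, Posterior]:
    """Merge one finding and return fresh posteriors over diagnosis nodes.

    Re-applying an identical finding is idempotent; re-assigning a node to
    a *different* state raises :class:`ConflictingEvidenceError`.
    """
    node = session.model.node(node_id)
    if state not in node.states:
        raise ValueError(f"node {node_id} has no state {state!r}")
    prior_state = session.evidence.get(node_id)
    if prior_state is not None and prior_state != state:
        raise ConflictingEvidenceError(
            f"node {node_id} already observed as {prior_state!r}, cannot re-assign to {state!r}"
        )
    merged = dict(session.evidence)
    merged[node_id] = state
    new_session = EvidenceSession(session.model, merged)
    from .model import NodeRole

    diagnosis_ids = [n.id for n in session.model.nodes_by_role(NodeRole.DIAGNOSIS)]
    return new_session, posterior(session.model, merged, diagnosis_ids)
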