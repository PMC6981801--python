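"""The inference pipeline: filter facts, match definitions, evaluate rules,
collect artifacts, format the report.

The pipeline is a single forward pass — fired artifacts do not become new
facts. Results are deterministic: fired artifacts are deduplicated by id
and ordered by (artifact-type priority, firing rule id), and the trace
records every aggregate rule's TriState together with its leaves'.
"""

from __future__ import annotations

import datetime as dt
import uuid
from dataclasses import dataclass

from ..errors import EvaluationError, KnowledgeBaseError
from ..facts import Fact, Quantity
from ..kb.rulebase import RuleKnowledgeBase, validate_kb
from ..terminology import CodedConcept
from .model import (
    ARTIFACT_PRIORITY,
    And,
    Condition,
    Definition,
    InferenceResult,
    Leaf,
    Not,
    Operation,
    OperationRule,
    Or,
    RuleTrace,
    TriState,
)


@dataclass(frozen=True)
class FilterPolicy:
    """Most-recent-per-concept filtering with an optional validity window.

    ``window`` bounds fact age relative to ``now``; ``None`` means
    unbounded (the default).
    """

    window: dt.timedelta | None = None
    now: dt.datetime | None = None


@dataclass
class MatchResult:
    matched: dict[Fact, Definition]
    unmatched: list[Fact]


def filter_facts(facts: set[Fact], policy: FilterPolicy = FilterPolicy()) -> set[Fact]:
    """Keep, per (subject, concept), only the most recent usable fact.

    Facts older than the policy window (when set) are dropped entirely.
    Ties on effective_time are broken deterministically by status value
    then repr, so identical inputs always give identical outputs.
    """
    usable = [f for f in facts if f.is_usable]
    if policy.window is not None:
        now = policy.now or dt.datetime.now(dt.timezone.utc)
        cutoff = now - policy.window
        usable = [f for f in usable if f.effective_time >= cutoff]
    best: dict[tuple, Fact] = {}
    for f in sorted(usable, key=lambda f: (f.effective_time, f.status.value, repr(f))):
        best[(f.subject_id, f.concept)] = f
    return set(best.values())


def match_definitions(facts: set[Fact], kb: RuleKnowledgeBase) -> MatchResult:
    """Map each fact to the Definition sharing its concept.

    Unmatched facts are reported, never dropped silently. Duplicate
    concepts across Definitions are a knowledge-base validation error
    upstream and cannot reach this point through :func:`run_inference`.
    """
    by_concept = {d.concept: d for d in kb.definitions.values()}
    matched, unmatched = {}, []
    for f in sorted(facts, key=repr):
        d = by_concept.get(f.concept)
        if d is None:
            unmatched.append(f)
        else:
            matched[f] = d
    return MatchResult(matched, unmatched)


def _compare(op: Operation, actual: float, reference) -> bool:
    if op is Operation.GT:
        return actual > reference
    if op is Operation.GE:
        return actual >= reference
    if op is Operation.LT:
        return actual < reference
    if op is Operation.LE:
        return actual <= reference
    if op is Operation.IN_RANGE:
        low, high = reference
        return low <= actual <= high
    raise AssertionError(op)


def evaluate_operation_rule(
    rule: OperationRule, facts: set[Fact], defs: dict[str, Definition] | RuleKnowledgeBase
) -> TriState:
    """Evaluate one operation rule against the (filtered) fact set.

    UNKNOWN when no fact matches the rule's Definition, when the fact is
    non-numeric under a numeric operation, or when the declared unit
    differs from the fact's. EXISTS is TRUE iff any usable matching fact
    exists and is never UNKNOWN.
    """
    definitions = defs.definitions if isinstance(defs, RuleKnowledgeBase) else defs
    definition = definitions.get(rule.definition_id)
    if definition is None:
        raise EvaluationError(f"operation rule {rule.id}: unresolved definition {rule.definition_id}")
    matching = [f for f in facts if f.is_usable and f.concept == definition.concept]

    if rule.operation is Operation.EXISTS:
        return TriState.of(bool(matching))
    if not matching:
        return TriState.UNKNOWN
    # Post-filter there is one fact per (subject, concept); be safe anyway.
    fact = max(matching, key=lambda f: (f.effective_time, repr(f)))

    if rule.is_numeric:
        if not isinstance(fact.value, Quantity):
            return TriState.UNKNOWN
        if rule.unit is not None and rule.unit != fact.value.unit:
            return TriState.UNKNOWN
        return TriState.of(_compare(rule.operation, fact.value.value, rule.value))

    # EQ / NE over quantity, coded, boolean or text values.
    if isinstance(fact.value, Quantity):
        if rule.unit is not None and rule.unit != fact.value.unit:
            return TriState.UNKNOWN
        try:
            same = fact.value.value == float(rule.value)
        except (TypeError, ValueError):
            return TriState.UNKNOWN
    elif isinstance(fact.value, CodedConcept):
        same = fact.value.code == str(rule.value)
    elif isinstance(fact.value, bool):
        same = fact.value is bool(rule.value)
    else:
        same = str(fact.value) == str(rule.value)
    return TriState.of(same if rule.operation is Operation.EQ else not same)


def evaluate_condition(tree: Condition, leaf_results: dict[str, TriState]) -> TriState:
    """Strong Kleene evaluation of an AND/OR/NOT tree, bottom-up."""
    if isinstance(tree, Leaf):
        if tree.op_rule_id not in leaf_results:
            raise EvaluationError(f"unresolved condition leaf: {tree.op_rule_id}")
        return leaf_results[tree.op_rule_id]
    if isinstance(tree, Not):
        return ~evaluate_condition(tree.child, leaf_results)
    if isinstance(tree, And):
        out = TriState.TRUE
        for c in tree.children:
            out = out & evaluate_condition(c, leaf_results)
        return out
    if isinstance(tree, Or):
        out = TriState.FALSE
        for c in tree.children:
            out = out | evaluate_condition(c, leaf_results)
        return out
    raise EvaluationError(f"unknown condition node: {tree!r}")


def evaluate_aggregate_rule(rule, leaf_results: dict[str, TriState]) -> TriState:
    return evaluate_condition(rule.condition, leaf_results)


def run_inference(
    kb: RuleKnowledgeBase,
    facts: set[Fact],
    policy: FilterPolicy = FilterPolicy(),
    transaction_id: str | None = None,
) -> InferenceResult:
    """Execute the full pipeline and return the artifacts that fired.

    An artifact fires only when some aggregate rule's condition is
    definitely TRUE; multiple rules concluding the same artifact fire it
    once. The result is invariant under fact-set and rule-declaration
    order.
    """
    report = validate_kb(kb)
    if not report.valid:
        raise KnowledgeBaseError(f"knowledge base {kb.id} failed validation", report)

    current = filter_facts(facts, policy)
    match_definitions(current, kb)  # surfaces unmatched facts in future tracing hooks

    leaf_results = {
        r.id: evaluate_operation_rule(r, current, kb) for r in kb.operation_rules.values()
    }

    trace: list[RuleTrace] = []
    firing: dict[str, str] = {}  # artifact id -> lowest firing rule id
    for ag in sorted(kb.aggregate_rules.values(), key=lambda r: r.id):
        state = evaluate_condition(ag.condition, leaf_results)
        trace.append(
            RuleTrace(ag.id, state, {l: leaf_results[l] for l in ag.condition.leaves()})
        )
        if state is TriState.TRUE:
            prior = firing.get(ag.artifact_id)
            if prior is None or ag.id < prior:
                firing[ag.artifact_id] = ag.id

    ordered = sorted(
        firing.items(),
        key=lambda item: (ARTIFACT_PRIORITY[kb.artifacts[item[0]].type], item[1]),
    )
    fired = [kb.artifacts[aid] for aid, _ in ordered]

    return InferenceResult(
        transaction_id=transaction_id or uuid.uuid4().hex,
        fired_artifacts=fired,
        trace=trace,
        facts_used=frozenset(current),
    )


def format_report(result: InferenceResult, kb: RuleKnowledgeBase) -> str:
    """Deterministic human-readable markdown report of an inference run.

    One titled section per artifact type present, artifact texts in firing
    order, transaction id in the footer. Identical results produce
    byte-identical documents.
    """
    lines = [f"# Decision support report for knowledge base {kb.id}", ""]
    current_type = None
    if not result.fired_artifacts:
        lines += ["No findings.", ""]
    for art in result.fired_artifacts:
        if art.type is not current_type:
            lines += [f"## {art.type.value}", ""]
            current_type = art.type
        text = art.text or f"({art.id})"
        lines += [f"- {text}", ""]
    lines += ["---", f"Transaction: {result.transaction_id}"]
    return "\n".join(lines) + "\n"
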