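"""Production-rule evaluation: three-valued logic, filtering, inference."""

import datetime as dt
import random

import pytest

import oracles
from conftest import make_fact
from fhircds.errors import EvaluationError, KnowledgeBaseError
from fhircds.facts import FactStatus
from fhircds.fixtures import generate_random_facts, generate_random_rule_kb
from fhircds.kb.io import kb_to_dict
from fhircds.kb.rulebase import RuleKnowledgeBase
from fhircds.rules import (
    AggregateRule,
    And,
    Artifact,
    ArtifactType,
    Definition,
    FilterPolicy,
    Leaf,
    Not,
    Operation,
    OperationRule,
    Or,
    TriState,
    condition_from_dict,
    evaluate_aggregate_rule,
    evaluate_operation_rule,
    filter_facts,
    format_report,
    match_definitions,
    run_inference,
)
from fhircds.terminology import CodedConcept, LOINC

_STATE = {"T": TriState.TRUE, "F": TriState.FALSE, "U": TriState.UNKNOWN}


def tiny_kb(**op_rules):
    """KB with one definition per operation rule, concept code == def id."""
    defs = []
    ops = []
    for op_id, (operation, value, unit) in op_rules.items():
        did = f"def-{op_id}"
        defs.append(Definition(did, CodedConcept(LOINC, did)))
        ops.append(OperationRule(op_id, did, operation, value, unit))
    arts = [Artifact("a", ArtifactType.DESCRIPTION, "fired")]
    if len(ops) >= 2:
        condition = And(tuple(Leaf(o.id) for o in ops))
    else:
        condition = Leaf(ops[0].id)
    ags = [AggregateRule("ag", condition, "a")]
    return RuleKnowledgeBase.build("tiny", defs, ops, ags, arts)


class TestKleeneLogic:
    def test_truth_tables_match_literal_tables_exhaustively(self):
        """Engine three-valued connectives equal the Kleene tables on every
        tree shape up to depth 3 over three leaves and all 3^3 assignments."""
        import itertools

        shapes = oracles.all_tree_shapes(["a", "b", "c"], max_depth=3)
        for shape in shapes:
            tree = condition_from_dict(shape)
            for combo in itertools.product("TFU", repeat=3):
                assignment = dict(zip("abc", combo))
                expected = oracles.kleene_eval(shape, assignment)
                got = evaluate_aggregate_rule(
                    AggregateRule("r", tree, "a"),
                    {k: _STATE[v] for k, v in assignment.items()},
                )
                assert got is _STATE[expected], (shape, assignment)

    def test_two_valued_trees_agree_with_boolean_evaluation(self):
        import itertools

        rng = random.Random(9)
        for _ in range(50):
            kb = generate_random_rule_kb(n_ops=8, depth=3, seed=rng.randint(0, 10**6))
            ag = next(iter(kb.aggregate_rules.values()))
            leaves = set(ag.condition.leaves())
            for combo in itertools.product([True, False], repeat=len(leaves)):
                assignment = dict(zip(sorted(leaves), combo))

                def boolean(node):
                    (key, payload), = node.items()
                    if key == "op":
                        return assignment[payload]
                    if key == "not":
                        return not boolean(payload)
                    vals = [boolean(c) for c in payload]
                    return all(vals) if key == "and" else any(vals)

                expected = TriState.of(boolean(ag.condition.to_dict()))
                got = evaluate_aggregate_rule(
                    ag, {k: TriState.of(v) for k, v in assignment.items()}
                )
                assert got is expected

    def test_unresolved_leaf_is_named_in_error(self):
        ag = AggregateRule("r", Leaf("ghost"), "a")
        with pytest.raises(EvaluationError, match="ghost"):
            evaluate_aggregate_rule(ag, {})


class TestFilterFacts:
    def test_latest_fact_per_concept_wins(self):
        older = make_fact("2345-7", 5.0, minutes=0)
        newer = make_fact("2345-7", 7.0, minutes=10)
        assert filter_facts({older, newer}) == {newer}

    def test_distinct_concepts_all_survive(self):
        facts = {make_fact(f"c{i}", float(i)) for i in range(5)}
        assert filter_facts(facts) == facts

    def test_validity_window_drops_stale_facts(self):
        now = dt.datetime(2024, 3, 15, tzinfo=dt.timezone.utc)
        fresh = make_fact("2345-7", 5.0, minutes=0)  # 14 days old
        stale = make_fact("718-7", 90.0, minutes=-26 * 24 * 60)  # 40 days old
        policy = FilterPolicy(window=dt.timedelta(days=30), now=now)
        assert filter_facts({fresh, stale}, policy) == {fresh}

    def test_entered_in_error_facts_never_survive(self):
        bad = make_fact("2345-7", 5.0, status=FactStatus.ENTERED_IN_ERROR)
        assert filter_facts({bad}) == set()

    def test_brute_force_max_by_time_oracle(self):
        rng = random.Random(17)
        facts = {
            make_fact(f"c{rng.randint(0, 3)}", rng.random(), minutes=rng.randint(0, 500))
            for _ in range(30)
        }
        survivors = filter_facts(facts)
        for f in survivors:
            same_key = [g for g in facts if g.concept == f.concept]
            assert f.effective_time == max(g.effective_time for g in same_key)


class TestMatchDefinitions:
    def test_fact_maps_to_definition_with_equal_concept(self):
        kb = tiny_kb(op1=(Operation.GT, 1.0, ""))
        fact = make_fact("def-op1", 2.0)
        result = match_definitions({fact}, kb)
        assert result.matched[fact].id == "def-op1"
        assert result.unmatched == []

    def test_unmatched_fact_is_reported_not_dropped(self):
        kb = tiny_kb(op1=(Operation.GT, 1.0, ""))
        fact = make_fact("9999-9", 2.0)
        result = match_definitions({fact}, kb)
        assert result.matched == {}
        assert result.unmatched == [fact]


class TestOperationRule:
    @pytest.mark.parametrize(
        "operation,ref,value,expected",
        [
            (Operation.GT, 1.0, 2.0, TriState.TRUE),
            (Operation.EQ, 0.0, 0.0, TriState.TRUE),
            (Operation.IN_RANGE, (3.9, 5.5), 7.2, TriState.FALSE),
            (Operation.LE, 5.0, 5.0, TriState.TRUE),
            (Operation.NE, 3.0, 3.0, TriState.FALSE),
        ],
    )
    def test_comparisons(self, operation, ref, value, expected):
        kb = tiny_kb(op1=(operation, ref, ""))
        fact = make_fact("def-op1", value)
        assert evaluate_operation_rule(kb.operation_rules["op1"], {fact}, kb) is expected

    def test_missing_fact_is_unknown(self):
        kb = tiny_kb(op1=(Operation.GT, 1.0, ""))
        assert evaluate_operation_rule(kb.operation_rules["op1"], set(), kb) is TriState.UNKNOWN

    def test_unit_mismatch_is_unknown_not_coerced(self):
        kb = tiny_kb(op1=(Operation.GT, 1.0, "mmol/L"))
        fact = make_fact("def-op1", 50.0, unit="mg/dL")
        assert evaluate_operation_rule(kb.operation_rules["op1"], {fact}, kb) is TriState.UNKNOWN

    def test_non_numeric_fact_under_numeric_op_is_unknown(self):
        kb = tiny_kb(op1=(Operation.GT, 1.0, ""))
        fact = make_fact("def-op1", "free text")
        assert evaluate_operation_rule(kb.operation_rules["op1"], {fact}, kb) is TriState.UNKNOWN

    def test_exists_is_never_unknown(self):
        kb = tiny_kb(op1=(Operation.EXISTS, None, None))
        rule = kb.operation_rules["op1"]
        assert evaluate_operation_rule(rule, set(), kb) is TriState.FALSE
        assert evaluate_operation_rule(rule, {make_fact("def-op1", "any")}, kb) is TriState.TRUE

    def test_exists_is_monotone_in_facts(self):
        kb = tiny_kb(op1=(Operation.EXISTS, None, None))
        rule = kb.operation_rules["op1"]
        facts = {make_fact("def-op1", 1.0)}
        assert evaluate_operation_rule(rule, facts, kb) is TriState.TRUE
        more = facts | {make_fact("other", 2.0), make_fact("def-op1", 3.0, minutes=9)}
        assert evaluate_operation_rule(rule, more, kb) is TriState.TRUE


class TestRunInference:
    def test_empty_fact_set_fires_nothing(self):
        kb = generate_random_rule_kb(n_ops=10, depth=3, seed=123)
        result = run_inference(kb, set())
        assert result.fired_artifacts == []
        for trace in result.trace:
            assert trace.result in (TriState.UNKNOWN, TriState.FALSE)

    def test_diabetes_risk_fixture_fires_high_risk(self, demo_kb):
        facts = {
            make_fact("2345-7", 7.2, unit="mmol/L"),
            make_fact("39156-5", 32.0, unit="kg/m2"),
        }
        result = run_inference(demo_kb, facts)
        assert [a.id for a in result.fired_artifacts] == ["art-t2d-high"]

    def test_no_artifact_fires_from_unknown_condition(self, demo_kb):
        # glucose present but BMI and age missing: high-risk rule is
        # TRUE AND UNKNOWN = UNKNOWN on both branches -> nothing fires
        facts = {make_fact("2345-7", 7.2, unit="mmol/L")}
        result = run_inference(demo_kb, facts)
        assert result.fired_artifacts == []
        assert any(t.result is TriState.UNKNOWN for t in result.trace)

    def test_firing_set_invariant_under_fact_permutation(self):
        kb = generate_random_rule_kb(n_ops=12, depth=3, seed=77)
        facts = generate_random_facts(kb, seed=78)
        reference = {a.id for a in run_inference(kb, facts).fired_artifacts}
        rng = random.Random(79)
        for _ in range(5):
            shuffled = list(facts)
            rng.shuffle(shuffled)
            assert {a.id for a in run_inference(kb, set(shuffled)).fired_artifacts} == reference

    def test_deterministic_results_including_trace(self):
        kb = generate_random_rule_kb(n_ops=10, depth=3, seed=55)
        facts = generate_random_facts(kb, seed=56)
        r1 = run_inference(kb, facts, transaction_id="t")
        r2 = run_inference(kb, facts, transaction_id="t")
        assert [a.id for a in r1.fired_artifacts] == [a.id for a in r2.fired_artifacts]
        assert [(t.rule_id, t.result, t.leaf_results) for t in r1.trace] == [
            (t.rule_id, t.result, t.leaf_results) for t in r2.trace
        ]

    def test_invalid_kb_is_refused_with_report(self):
        kb = tiny_kb(op1=(Operation.GT, 1.0, ""))
        kb.aggregate_rules["bad"] = AggregateRule("bad", Leaf("missing-op"), "a")
        with pytest.raises(KnowledgeBaseError) as exc_info:
            run_inference(kb, set())
        assert not exc_info.value.report.valid

    def test_same_artifact_from_two_rules_fires_once(self):
        defs = [Definition("d1", CodedConcept(LOINC, "d1"))]
        ops = [OperationRule("op1", "d1", Operation.GT, 1.0, "")]
        arts = [Artifact("a", ArtifactType.DESCRIPTION, "only once")]
        ags = [
            AggregateRule("ag1", Leaf("op1"), "a"),
            AggregateRule("ag2", Not(Not(Leaf("op1"))), "a"),
        ]
        kb = RuleKnowledgeBase.build("dup", defs, ops, ags, arts)
        result = run_inference(kb, {make_fact("d1", 5.0)})
        assert [a.id for a in result.fired_artifacts] == ["a"]

    def test_artifact_ordering_follows_type_priority(self):
        defs = [Definition("d1", CodedConcept(LOINC, "d1"))]
        ops = [OperationRule("op1", "d1", Operation.GT, 1.0, "")]
        arts = [
            Artifact("rec", ArtifactType.RECOMMENDATION, "recommendation"),
            Artifact("scale", ArtifactType.SCALE, "scale result"),
            Artifact("risk", ArtifactType.RISK, "risk text"),
        ]
        ags = [
            AggregateRule("ag1", Leaf("op1"), "rec"),
            AggregateRule("ag2", Leaf("op1"), "scale"),
            AggregateRule("ag3", Leaf("op1"), "risk"),
        ]
        kb = RuleKnowledgeBase.build("order", defs, ops, ags, arts)
        result = run_inference(kb, {make_fact("d1", 5.0)})
        assert [a.id for a in result.fired_artifacts] == ["scale", "risk", "rec"]


class TestOracleEquivalence:
    def test_fired_artifacts_match_naive_evaluator(self):
        """Engine firing sets equal an independent evaluator's over random
        knowledge bases and fact sets."""
        rng = random.Random(2024)
        for _ in range(60):
            kb = generate_random_rule_kb(
                n_ops=rng.randint(1, 20), depth=rng.randint(1, 4),
                seed=rng.randint(0, 10**6), n_aggregates=rng.randint(1, 8),
            )
            facts = generate_random_facts(kb, seed=rng.randint(0, 10**6),
                                          p_present=rng.uniform(0.2, 1.0))
            engine = {a.id for a in run_inference(kb, facts).fired_artifacts}
            naive = oracles.naive_fired_artifact_ids(
                kb_to_dict(kb), [f.as_dict() for f in facts]
            )
            assert engine == naive


class TestFormatReport:
    def test_recommendation_section_and_text_present(self):
        defs = [Definition("d1", CodedConcept(LOINC, "d1"))]
        ops = [OperationRule("op1", "d1", Operation.EXISTS, None)]
        arts = [Artifact("a", ArtifactType.RECOMMENDATION, "drink water")]
        kb = RuleKnowledgeBase.build(
            "r", defs, ops, [AggregateRule("ag", Leaf("op1"), "a")], arts
        )
        result = run_inference(kb, {make_fact("d1", 1.0)}, transaction_id="tx")
        doc = format_report(result, kb)
        assert "## Recommendation" in doc
        assert "drink water" in doc
        assert "tx" in doc

    def test_identical_results_give_byte_identical_documents(self, demo_kb):
        facts = {make_fact("718-7", 95.0, unit="g/L"), make_fact("2276-4", 8.0, unit="ug/L")}
        r1 = run_inference(demo_kb, facts, transaction_id="t1")
        r2 = run_inference(demo_kb, facts, transaction_id="t1")
        assert format_report(r1, demo_kb) == format_report(r2, demo_kb)

    def test_each_fired_text_appears_exactly_once(self):
        rng = random.Random(31)
        for _ in range(10):
            kb = generate_random_rule_kb(10, 3, rng.randint(0, 10**6))
            facts = generate_random_facts(kb, rng.randint(0, 10**6))
            result = run_inference(kb, facts)
            doc = format_report(result, kb)
            for art in result.fired_artifacts:
                assert doc.count(art.text) == 1
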