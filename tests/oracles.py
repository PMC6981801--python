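"""Independent oracles used by the test suite.

These deliberately avoid the package's evaluation code paths: the rule
oracle interprets the *serialized dict form* of a knowledge base with its
own comparison logic, the Kleene oracle is literal truth tables, and the
Bayes oracle conditions a brute-force joint. They exist so the engines are
checked against something that cannot share their bugs.
"""

from __future__ import annotations

import itertools

# --- three-valued logic: literal truth tables ------------------------------

T, F, U = "T", "F", "U"

NOT_TABLE = {T: F, F: T, U: U}
AND_TABLE = {
    (T, T): T, (T, F): F, (T, U): U,
    (F, T): F, (F, F): F, (F, U): F,
    (U, T): U, (U, F): F, (U, U): U,
}
OR_TABLE = {
    (T, T): T, (T, F): T, (T, U): T,
    (F, T): T, (F, F): F, (F, U): U,
    (U, T): T, (U, F): U, (U, U): U,
}


def kleene_eval(tree, assignment: dict[str, str]) -> str:
    """Evaluate a nested {and/or/not/op} dict with the literal tables."""
    (key, payload), = tree.items()
    if key == "op":
        return assignment[payload]
    if key == "not":
        return NOT_TABLE[kleene_eval(payload, assignment)]
    values = [kleene_eval(c, assignment) for c in payload]
    table = AND_TABLE if key == "and" else OR_TABLE
    out = values[0]
    for v in values[1:]:
        out = table[(out, v)]
    return out


# --- naive production-rule evaluator ---------------------------------------


def _naive_op_state(rule: dict, defs: dict[str, dict], fact_dicts: list[dict]) -> str:
    """Evaluate one serialized operation rule over serialized facts."""
    concept = defs[rule["definition_id"]]["concept"]
    matches = [
        f for f in fact_dicts
        if f["status"] != "entered-in-error"
        and f["concept"]["system"] == concept["system"]
        and f["concept"]["code"] == concept["code"]
    ]
    op = rule["operation"]
    if op == "EXISTS":
        return T if matches else F
    if not matches:
        return U
    fact = max(matches, key=lambda f: (f["effective_time"], repr(f)))
    value = fact["value"]
    if op in ("GT", "GE", "LT", "LE", "IN_RANGE"):
        if "quantity" not in value:
            return U
        if rule.get("unit") is not None and rule["unit"] != value["unit"]:
            return U
        x = value["quantity"]
        ref = rule["value"]
        ok = {
            "GT": lambda: x > ref,
            "GE": lambda: x >= ref,
            "LT": lambda: x < ref,
            "LE": lambda: x <= ref,
            "IN_RANGE": lambda: ref[0] <= x <= ref[1],
        }[op]()
        return T if ok else F
    # EQ / NE
    if "quantity" in value:
        if rule.get("unit") is not None and rule["unit"] != value["unit"]:
            return U
        same = value["quantity"] == float(rule["value"])
    elif "coded" in value:
        same = value["coded"]["code"] == str(rule["value"])
    elif "boolean" in value:
        same = value["boolean"] is bool(rule["value"])
    else:
        same = value["text"] == str(rule["value"])
    if op == "EQ":
        return T if same else F
    return F if same else T


def naive_fired_artifact_ids(kb_doc: dict, fact_dicts: list[dict]) -> set[str]:
    """Fired-artifact id set by naive enumeration over the serialized KB."""
    defs = {d["id"]: d for d in kb_doc["definitions"]}
    op_states = {
        r["id"]: _naive_op_state(r, defs, fact_dicts) for r in kb_doc["operation_rules"]
    }
    fired = set()
    for ag in kb_doc["aggregate_rules"]:
        if kleene_eval(ag["condition"], op_states) == T:
            fired.add(ag["artifact_id"])
    return fired


# --- Bayes: brute-force conditioning of the enumerated joint ----------------


def brute_posterior(model, joint: dict, evidence: dict, query: str) -> dict[str, float]:
    """P(query | evidence) by summing consistent joint entries."""
    pos = {nid: i for i, nid in enumerate(model.node_ids)}

    def consistent(combo):
        return all(combo[pos[k]] == v for k, v in evidence.items())

    z = sum(p for combo, p in joint.items() if consistent(combo))
    states = model.node(query).states
    return {
        s: sum(
            p for combo, p in joint.items() if consistent(combo) and combo[pos[query]] == s
        ) / z
        for s in states
    }


# --- condition-tree shape enumeration ---------------------------------------


def _leaf_count(tree) -> int:
    (key, payload), = tree.items()
    if key == "op":
        return 1
    if key == "not":
        return _leaf_count(payload)
    return sum(_leaf_count(c) for c in payload)


def all_tree_shapes(variables: list[str], max_depth: int, max_leaves: int = 3) -> list[dict]:
    """Every {and/or/not/op} tree up to ``max_depth`` over the variables,
    with binary and/or and at most ``max_leaves`` leaves — an exhaustive
    finite family."""
    def build(depth):
        shapes = [{"op": v} for v in variables]
        if depth == 0:
            return shapes
        subs = build(depth - 1)
        out = list(shapes)
        out.extend({"not": s} for s in subs)
        for a, b in itertools.product(subs, repeat=2):
            if _leaf_count(a) + _leaf_count(b) <= max_leaves:
                out.append({"and": [a, b]})
                out.append({"or": [a, b]})
        return out

    # structural dedup (identical shapes arise at multiple depths)
    seen, unique = set(), []
    for t in build(max_depth):
        key = repr(t)
        if key not in seen:
            seen.add(key)
            unique.append(t)
    return unique
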