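"""File dialect for rule knowledge bases and Bayesian models.

Both are YAML (JSON, being a YAML subset, loads through the same path).
A rule KB file carries top-level lists ``definitions``, ``operation_rules``,
``aggregate_rules``, ``artifacts``; condition trees are nested
``{"and": [...]}`` / ``{"or": [...]}`` / ``{"not": ...}`` / ``{"op": id}``
objects. A model file carries ``nodes`` (with per-row CPTs, strata and
code-to-state maps) and a ``validation`` block with expert signoffs.

Unknown top-level keys produce a warning and are preserved verbatim on
save; ``load(save(x)) == x`` for every well-formed entity.
"""

from __future__ import annotations

import io
import os

import yaml

from ..errors import ParseError
from ..rules.model import (
    AggregateRule,
    Artifact,
    ArtifactType,
    Definition,
    Operation,
    OperationRule,
    condition_from_dict,
)
from ..bayes.model import (
    BayesianModel,
    BayesNode,
    CptRow,
    ModelValidation,
    NodeRole,
    Stratum,
    ValidationStatus,
)
from ..terminology import CodedConcept
from .rulebase import RuleKnowledgeBase

_KB_KEYS = {"id", "version", "metadata", "definitions", "operation_rules",
            "aggregate_rules", "artifacts"}
_MODEL_KEYS = {"id", "version", "metadata", "nodes", "validation"}
_EXTRA = "__extra__"


def _load_yaml(text: str, source: str) -> dict:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark else ""
        raise ParseError(f"{source}: malformed YAML{where}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{source}: expected a mapping at top level")
    return doc


def _concept(d: dict) -> CodedConcept:
    return CodedConcept(system=d["system"], code=str(d["code"]), display=d.get("display"))


# --- rule knowledge bases ---------------------------------------------------


def kb_from_dict(doc: dict, source: str = "<kb>") -> tuple[RuleKnowledgeBase, list[str]]:
    warnings = []
    for section in ("definitions", "operation_rules", "aggregate_rules", "artifacts"):
        if section not in doc:
            raise ParseError(f"{source}: missing required section {section!r}")
    extra = {k: v for k, v in doc.items() if k not in _KB_KEYS}
    for k in extra:
        warnings.append(f"unknown top-level key {k!r} preserved")
    metadata = dict(doc.get("metadata") or {})
    if extra:
        metadata[_EXTRA] = extra

    definitions = [
        Definition(id=d["id"], concept=_concept(d["concept"])) for d in doc["definitions"]
    ]
    op_rules = []
    for r in doc["operation_rules"]:
        op = Operation(r["operation"])
        value = r.get("value")
        if op is Operation.IN_RANGE:
            value = tuple(value)
        op_rules.append(
            OperationRule(
                id=r["id"],
                definition_id=r["definition_id"],
                operation=op,
                value=value,
                unit=r.get("unit"),
                nomenclature=r.get("nomenclature", ""),
                code=str(r.get("code", "")),
                name=r.get("name", ""),
            )
        )
    ag_rules = [
        AggregateRule(
            id=r["id"],
            condition=condition_from_dict(r["condition"]),
            artifact_id=r["artifact_id"],
        )
        for r in doc["aggregate_rules"]
    ]
    artifacts = [
        Artifact(
            id=a["id"],
            type=ArtifactType(a["type"]),
            text=a.get("text", ""),
            concept=_concept(a["concept"]) if a.get("concept") else None,
            payload=tuple(a.get("payload", ())),
        )
        for a in doc["artifacts"]
    ]
    kb = RuleKnowledgeBase.build(
        id=doc.get("id", "kb"),
        definitions=definitions,
        operation_rules=op_rules,
        aggregate_rules=ag_rules,
        artifacts=artifacts,
        version=int(doc.get("version", 1)),
        metadata=metadata,
    )
    return kb, warnings


def kb_to_dict(kb: RuleKnowledgeBase) -> dict:
    metadata = {k: v for k, v in kb.metadata.items() if k != _EXTRA}
    doc = {
        "id": kb.id,
        "version": kb.version,
        "definitions": [
            {"id": d.id, "concept": d.concept.as_dict()} for d in kb.definitions.values()
        ],
        "operation_rules": [
            _op_rule_dict(r) for r in kb.operation_rules.values()
        ],
        "aggregate_rules": [
            {"id": r.id, "condition": r.condition.to_dict(), "artifact_id": r.artifact_id}
            for r in kb.aggregate_rules.values()
        ],
        "artifacts": [_artifact_dict(a) for a in kb.artifacts.values()],
    }
    if metadata:
        doc["metadata"] = metadata
    doc.update(kb.metadata.get(_EXTRA, {}))
    return doc


def _op_rule_dict(r: OperationRule) -> dict:
    out = {"id": r.id, "definition_id": r.definition_id, "operation": r.operation.value}
    if r.value is not None:
        out["value"] = list(r.value) if r.operation is Operation.IN_RANGE else r.value
    if r.unit is not None:
        out["unit"] = r.unit
    for fld in ("nomenclature", "code", "name"):
        if getattr(r, fld):
            out[fld] = getattr(r, fld)
    return out


def _artifact_dict(a: Artifact) -> dict:
    out = {"id": a.id, "type": a.type.value}
    if a.text:
        out["text"] = a.text
    if a.concept is not None:
        out["concept"] = a.concept.as_dict()
    if a.payload:
        out["payload"] = list(a.payload)
    return out


def load_kb_file(path: str | os.PathLike) -> RuleKnowledgeBase:
    with open(path, "r", encoding="utf-8") as fh:
        kb, _ = kb_from_dict(_load_yaml(fh.read(), str(path)), str(path))
    return kb


def save_kb_file(kb: RuleKnowledgeBase, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(kb_to_dict(kb), fh, sort_keys=False, allow_unicode=True)


# --- Bayesian models --------------------------------------------------------


def model_from_dict(doc: dict, source: str = "<model>") -> tuple[BayesianModel, list[str]]:
    warnings = []
    if "nodes" not in doc:
        raise ParseError(f"{source}: missing required section 'nodes'")
    extra = {k: v for k, v in doc.items() if k not in _MODEL_KEYS}
    for k in extra:
        warnings.append(f"unknown top-level key {k!r} preserved")
    metadata = dict(doc.get("metadata") or {})
    if extra:
        metadata[_EXTRA] = extra

    nodes = []
    for n in doc["nodes"]:
        cpt = tuple(
            CptRow.make(dict(row.get("given") or {}), dict(row["p"]))
            for row in n.get("cpt", [])
        )
        strata = tuple(
            Stratum(state=s["state"], low=s.get("low"), high=s.get("high"))
            for s in n.get("strata", [])
        )
        nodes.append(
            BayesNode(
                id=n["id"],
                concept=_concept(n["concept"]),
                role=NodeRole(n["role"]),
                states=tuple(n["states"]),
                parents=tuple(n.get("parents", ())),
                cpt=cpt,
                strata=strata,
                state_codes=tuple(dict(n.get("state_codes") or {}).items()),
                positive_state=n.get("positive_state"),
            )
        )
    vdoc = doc.get("validation") or {}
    validation = ModelValidation(
        status=ValidationStatus(vdoc.get("status", "prototype")),
        signoffs=list(vdoc.get("signoffs", [])),
    )
    model = BayesianModel(
        id=doc.get("id", "model"),
        nodes=nodes,
        validation=validation,
        version=int(doc.get("version", 1)),
        metadata=metadata,
    )
    return model, warnings


def model_to_dict(model: BayesianModel) -> dict:
    metadata = {k: v for k, v in model.metadata.items() if k != _EXTRA}
    nodes = []
    for n in model.nodes:
        nd: dict = {
            "id": n.id,
            "concept": n.concept.as_dict(),
            "role": n.role.value,
            "states": list(n.states),
        }
        if n.parents:
            nd["parents"] = list(n.parents)
        nd["cpt"] = [
            {"given": dict(r.given), "p": dict(r.probabilities)} for r in n.cpt
        ]
        if n.strata:
            nd["strata"] = [
                {k: v for k, v in
                 (("state", s.state), ("low", s.low), ("high", s.high)) if v is not None}
                for s in n.strata
            ]
        if n.state_codes:
            nd["state_codes"] = dict(n.state_codes)
        if n.positive_state:
            nd["positive_state"] = n.positive_state
        nodes.append(nd)
    doc = {
        "id": model.id,
        "version": model.version,
        "nodes": nodes,
        "validation": {
            "status": model.validation.status.value,
            "signoffs": list(model.validation.signoffs),
        },
    }
    if metadata:
        doc["metadata"] = metadata
    doc.update(model.metadata.get(_EXTRA, {}))
    return doc


def load_model_file(path: str | os.PathLike) -> BayesianModel:
    with open(path, "r", encoding="utf-8") as fh:
        model, _ = model_from_dict(_load_yaml(fh.read(), str(path)), str(path))
    return model


def save_model_file(model: BayesianModel, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False, allow_unicode=True)


def dumps_entity(kind: str, entity) -> str:
    doc = kb_to_dict(entity) if kind == "rule_kb" else model_to_dict(entity)
    buf = io.StringIO()
    yaml.safe_dump(doc, buf, sort_keys=False, allow_unicode=True)
    return buf.getvalue()


def loads_entity(kind: str, text: str):
    doc = _load_yaml(text, f"<{kind}>")
    if kind == "rule_kb":
        return kb_from_dict(doc)[0]
    return model_from_dict(doc)[0]
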