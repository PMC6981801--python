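"""Versioned knowledge store with an audit log.

An embedded document store: entities (rule knowledge bases and Bayesian
models) are kept as serialized YAML per version — past versions are
immutable and version numbers are gapless per entity. When given a root
directory the layout is ``<root>/<kind>/<id>/<version>.yaml`` plus an
append-only ``audit.jsonl``; without one the store is purely in-memory.

Writes are validated first (an invalid entity is rejected with its
validation report) and guarded against stale-version races: a caller citing
a non-latest base version gets a conflict, not a silent overwrite.
"""

from __future__ import annotations

import datetime as dt
import json
import os
from pathlib import Path

from ..errors import KnowledgeBaseError, NotFoundError, StoreConflictError
from ..bayes.model import validate_model
from ..terminology import CodedConcept
from .io import dumps_entity, loads_entity
from .rulebase import validate_kb

RULE_KB = "rule_kb"
BAYES_MODEL = "bayes_model"
_KINDS = (RULE_KB, BAYES_MODEL)

_VALIDATORS = {RULE_KB: validate_kb, BAYES_MODEL: validate_model}


class KnowledgeStore:
    def __init__(self, root: str | os.PathLike | None = None):
        self.root = Path(root) if root is not None else None
        # kind -> id -> [serialized v1, v2, ...]
        self._data: dict[str, dict[str, list[str]]] = {k: {} for k in _KINDS}
        self._audit: list[dict] = []
        if self.root is not None:
            self.root.mkdir(parents=True, exist_ok=True)
            self._load_from_disk()

    # -- persistence -------------------------------------------------------

    def _load_from_disk(self) -> None:
        for kind in _KINDS:
            kind_dir = self.root / kind
            if not kind_dir.is_dir():
                continue
            for entity_dir in sorted(kind_dir.iterdir()):
                if not entity_dir.is_dir():
                    continue
                versions = sorted(
                    entity_dir.glob("*.yaml"), key=lambda p: int(p.stem)
                )
                self._data[kind][entity_dir.name] = [
                    p.read_text(encoding="utf-8") for p in versions
                ]
        audit = self.root / "audit.jsonl"
        if audit.exists():
            self._audit = [
                json.loads(line)
                for line in audit.read_text(encoding="utf-8").splitlines()
                if line.strip()
            ]

    def _persist(self, kind: str, entity_id: str, version: int, text: str) -> None:
        if self.root is None:
            return
        entity_dir = self.root / kind / entity_id
        entity_dir.mkdir(parents=True, exist_ok=True)
        (entity_dir / f"{version}.yaml").write_text(text, encoding="utf-8")

    def _log(self, actor: str, summary: str) -> None:
        entry = {
            "timestamp": dt.datetime.now(dt.timezone.utc).isoformat(),
            "actor": actor,
            "summary": summary,
        }
        self._audit.append(entry)
        if self.root is not None:
            with open(self.root / "audit.jsonl", "a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry) + "\n")

    # -- CRUD --------------------------------------------------------------

    def put_entity(
        self, kind: str, entity, actor: str = "system",
        expected_version: int | None = None,
    ) -> int:
        """Store a validated entity as the next version; returns the version.

        ``expected_version`` enables optimistic concurrency: citing a
        non-latest base version raises :class:`StoreConflictError`.
        """
        if kind not in _KINDS:
            raise ValueError(f"unknown entity kind: {kind!r}")
        report = _VALIDATORS[kind](entity)
        if not report.valid:
            raise KnowledgeBaseError(
                f"{kind} {entity.id!r} failed validation", report
            )
        versions = self._data[kind].setdefault(entity.id, [])
        latest = len(versions)
        if expected_version is not None and expected_version != latest:
            raise StoreConflictError(
                f"{kind} {entity.id!r}: stale write against version "
                f"{expected_version}, latest is {latest}"
            )
        new_version = latest + 1
        entity.version = new_version
        text = dumps_entity(kind, entity)
        versions.append(text)
        self._persist(kind, entity.id, new_version, text)
        self._log(actor, f"put {kind} {entity.id} v{new_version}")
        return new_version

    def get_entity(self, kind: str, entity_id: str, version: int | None = None):
        """Fetch an entity (latest version when ``version`` is omitted)."""
        if kind not in _KINDS:
            raise ValueError(f"unknown entity kind: {kind!r}")
        versions = self._data[kind].get(entity_id)
        if not versions:
            raise NotFoundError(f"{kind} {entity_id!r} not found")
        if version is None:
            version = len(versions)
        if not 1 <= version <= len(versions):
            raise NotFoundError(f"{kind} {entity_id!r} has no version {version}")
        return loads_entity(kind, versions[version - 1])

    def latest_version(self, kind: str, entity_id: str) -> int:
        versions = self._data[kind].get(entity_id)
        if not versions:
            raise NotFoundError(f"{kind} {entity_id!r} not found")
        return len(versions)

    def raw_bytes(self, kind: str, entity_id: str, version: int) -> str:
        """Serialized text of a stored version (immutability checks)."""
        return self._data[kind][entity_id][version - 1]

    def ids(self, kind: str) -> list[str]:
        return sorted(self._data[kind])

    # -- lookup ------------------------------------------------------------

    def query_by_concept(self, concept: CodedConcept) -> list[tuple[str, str, str]]:
        """All entities referencing a concept, as (kind, entity id, element id).

        Covers Definitions, OperationRules (through their Definition) and
        Bayesian nodes; searches latest versions only. Result order is
        deterministic and independent of insertion order.
        """
        hits: list[tuple[str, str, str]] = []
        for kb_id in self.ids(RULE_KB):
            kb = self.get_entity(RULE_KB, kb_id)
            matching_defs = {
                d.id for d in kb.definitions.values() if d.concept == concept
            }
            hits.extend((RULE_KB, kb_id, f"definition:{d}") for d in sorted(matching_defs))
            hits.extend(
                (RULE_KB, kb_id, f"operation_rule:{r.id}")
                for r in kb.operation_rules.values()
                if r.definition_id in matching_defs
            )
        for model_id in self.ids(BAYES_MODEL):
            model = self.get_entity(BAYES_MODEL, model_id)
            hits.extend(
                (BAYES_MODEL, model_id, f"node:{n.id}")
                for n in model.nodes
                if n.concept == concept
            )
        return sorted(hits)

    @property
    def audit_log(self) -> list[dict]:
        return list(self._audit)
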