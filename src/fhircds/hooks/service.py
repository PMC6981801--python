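"""The CDS manager: service directory, invocation, proxying, statistics.

Realizes the service-facing side of the platform in one process: a
registry of CDS services (each bound to a rule knowledge base or an
accepted Bayesian model in the knowledge store), CDS Hooks 1.0 discovery
and invocation, per-service usage counters, health checks, an in-process
event log, and a transaction log in which every request's records share
one transaction id.
"""

from __future__ import annotations

import datetime as dt
import shutil
import time
import uuid

from ..errors import (
    AdapterError,
    InconsistentEvidenceError,
    ModelNotAcceptedError,
    NotFoundError,
    ParseError,
)
from ..bayes.inference import posterior
from ..bayes.interpret import interpret_facts, rank_diagnoses
from ..bayes.model import NodeRole
from ..fhir.adapter import extract_facts
from ..fhir.resources import FhirResource, parse_resource
from ..kb.store import BAYES_MODEL, RULE_KB, KnowledgeStore
from ..rules.engine import FilterPolicy, run_inference
from ..rules.model import Artifact, ArtifactType
from .model import (
    Card,
    CDSRequest,
    CDSServiceDescriptor,
    CheckStatus,
    HealthCheck,
    HealthStatus,
    Indicator,
    Suggestion,
    TransactionLogEntry,
)

_SUMMARY_LIMIT = 140

_INDICATOR_BY_TYPE = {
    ArtifactType.SCALE: Indicator.INFO,
    ArtifactType.RISK: Indicator.WARNING,
    ArtifactType.DIAGNOSIS: Indicator.INFO,
    ArtifactType.DIAGNOSTIC_REPORT: Indicator.INFO,
    ArtifactType.REFERRAL_REQUEST: Indicator.INFO,
    ArtifactType.PROCEDURE_REQUEST: Indicator.INFO,
    ArtifactType.DIAGNOSTIC_REQUEST: Indicator.INFO,
    ArtifactType.DESCRIPTION: Indicator.INFO,
    ArtifactType.RECOMMENDATION: Indicator.INFO,
    ArtifactType.BEHAVIOR_RECOMMENDATION: Indicator.INFO,
}

_SUGGESTION_TYPES = {
    ArtifactType.REFERRAL_REQUEST,
    ArtifactType.PROCEDURE_REQUEST,
    ArtifactType.DIAGNOSTIC_REQUEST,
}


def truncate_summary(text: str, limit: int = _SUMMARY_LIMIT) -> str:
    """Truncate at a word boundary with a trailing ellipsis, ≤ ``limit`` chars."""
    if len(text) <= limit:
        return text
    cut = text[: limit - 1]
    space = cut.rfind(" ")
    if space > 0:
        cut = cut[:space]
    return cut + "…"


def artifact_to_card(artifact: Artifact, source_label: str = "fhircds") -> Card:
    """Fixed artifact-type-to-card mapping.

    Risk artifacts warn; a Diagnosis marked urgent in its payload is
    critical; the three request types carry one suggestion; everything
    else is informational. The summary is the artifact text truncated at
    a word boundary, with the full text in the detail when truncated.
    """
    indicator = _INDICATOR_BY_TYPE[artifact.type]
    if artifact.type is ArtifactType.DIAGNOSIS and "urgent" in artifact.payload:
        indicator = Indicator.CRITICAL
    text = artifact.text or f"({artifact.id})"
    summary = truncate_summary(text)
    detail = text if summary != text else None
    suggestions = ()
    if artifact.type in _SUGGESTION_TYPES:
        suggestions = (Suggestion(label=truncate_summary(text)),)
    return Card(
        summary=summary,
        indicator=indicator,
        source_label=source_label,
        detail=detail,
        suggestions=suggestions,
    )


class CDSManager:
    """Service directory + proxy over the knowledge store's engines."""

    def __init__(self, store: KnowledgeStore, filter_policy: FilterPolicy = FilterPolicy()):
        self.store = store
        self.filter_policy = filter_policy
        self._services: dict[str, CDSServiceDescriptor] = {}
        self._stats: dict[str, dict[str, int]] = {}
        self.transaction_log: list[TransactionLogEntry] = []
        self.event_log: list[dict] = []
        self._health_checks: list = []

    # -- registry ----------------------------------------------------------

    def register_service(self, descriptor: CDSServiceDescriptor) -> list[dict]:
        """Register (or replace) a service; returns the updated catalog.

        A Bayesian binding must be an *accepted* model — two-expert
        consensus is the deployment gate.
        """
        entity = self.store.get_entity(descriptor.engine_kind, descriptor.engine_id)
        if descriptor.engine_kind == BAYES_MODEL and not entity.validation.accepted:
            raise ModelNotAcceptedError(
                f"model {descriptor.engine_id!r} is not accepted for production "
                f"(status={entity.validation.status.value}); two-expert consensus required"
            )
        self._services[descriptor.service_id] = descriptor
        self._stats.setdefault(
            descriptor.service_id, {"calls": 0, "errors": 0, "cards": 0}
        )
        return self.discovery()["services"]

    def discovery(self) -> dict:
        """CDS Hooks 1.0 discovery document, deterministically ordered."""
        return {
            "services": [
                self._services[sid].to_discovery() for sid in sorted(self._services)
            ]
        }

    # -- invocation --------------------------------------------------------

    def invoke_service(self, service_id: str, request: CDSRequest | dict) -> list[Card]:
        """Run the bound engine on the request's prefetched data.

        Facts come from the prefetch bundle(s), falling back to a bare
        patient context when no prefetch is supplied; missing data flows
        through the engines' UNKNOWN semantics. An empty card list is a
        valid outcome. Inconsistent Bayesian evidence surfaces as a
        warning card rather than an error.
        """
        if service_id not in self._services:
            raise NotFoundError(f"unknown CDS service: {service_id!r}")
        if isinstance(request, dict):
            request = CDSRequest.from_dict(request)
        descriptor = self._services[service_id]
        transaction_id = uuid.uuid4().hex
        started = time.perf_counter()
        try:
            bundle = self._assemble_bundle(request)
            facts = extract_facts(bundle)
            source = self._source_label(descriptor)
            if descriptor.engine_kind == RULE_KB:
                kb = self.store.get_entity(RULE_KB, descriptor.engine_id)
                result = run_inference(
                    kb, facts, self.filter_policy, transaction_id=transaction_id
                )
                cards = [artifact_to_card(a, source) for a in result.fired_artifacts]
            else:
                cards = self._invoke_bayes(descriptor, facts, source, transaction_id)
        except InconsistentEvidenceError as exc:
            cards = [
                Card(
                    summary=truncate_summary(f"Findings are inconsistent with the model: {exc}"),
                    indicator=Indicator.WARNING,
                    source_label=self._source_label(descriptor),
                )
            ]
            self._record(transaction_id, service_id, "ok", started, cards=cards)
            return cards
        except Exception as exc:
            self._record(transaction_id, service_id, "error", started, error=str(exc))
            raise
        self._record(transaction_id, service_id, "ok", started, cards=cards)
        return cards

    def _invoke_bayes(self, descriptor, facts, source, transaction_id) -> list[Card]:
        model = self.store.get_entity(BAYES_MODEL, descriptor.engine_id)
        if not model.validation.accepted:
            raise ModelNotAcceptedError(
                f"model {descriptor.engine_id!r} lost accepted status"
            )
        interp = interpret_facts(facts, model)
        diagnosis_ids = [n.id for n in model.nodes_by_role(NodeRole.DIAGNOSIS)]
        post = posterior(model, interp.evidence, diagnosis_ids)
        ranked, _ = rank_diagnoses(post, model, transaction_id)
        if not ranked:
            return []
        top = ranked[0]
        detail_lines = [
            f"- {r.node.concept.display or r.node.id}: "
            f"P({r.node.positive} | findings) = {r.probability:.3f}"
            for r in ranked
        ]
        summary = truncate_summary(
            f"Most likely: {top.node.concept.display or top.node.id} "
            f"(P = {top.probability:.2f})"
        )
        return [
            Card(
                summary=summary,
                indicator=Indicator.INFO,
                source_label=source,
                detail="\n".join(detail_lines),
            )
        ]

    def _assemble_bundle(self, request: CDSRequest) -> FhirResource:
        """Merge prefetch entries (bundles or single resources) into one
        bundle, synthesizing the Patient from context when absent."""
        entries: list[dict] = []
        has_patient = False
        for token in sorted(request.prefetch):
            payload = request.prefetch[token]
            res = parse_resource(payload) if not isinstance(payload, FhirResource) else payload
            if res.resource_type == "Bundle":
                for entry in res.content.get("entry", []):
                    inner = entry.get("resource", {})
                    entries.append({"resource": inner})
                    if inner.get("resourceType") == "Patient":
                        has_patient = True
            else:
                entries.append({"resource": res.content})
                if res.resource_type == "Patient":
                    has_patient = True
        if not has_patient:
            pid = request.patient_id
            if not pid:
                raise AdapterError(
                    "request carries neither a prefetched Patient nor context.patientId"
                )
            entries.insert(0, {"resource": {"resourceType": "Patient", "id": pid}})
        return parse_resource(
            {"resourceType": "Bundle", "type": "collection", "entry": entries}
        )

    def _source_label(self, descriptor: CDSServiceDescriptor) -> str:
        try:
            entity = self.store.get_entity(descriptor.engine_kind, descriptor.engine_id)
            label = entity.metadata.get("provenance")
            if label:
                return f"{descriptor.title or descriptor.service_id} — {label}"
        except Exception:
            pass
        return descriptor.title or descriptor.service_id

    # -- proxying & statistics ---------------------------------------------

    def proxy_call(self, service_id: str, request: CDSRequest | dict) -> list[Card]:
        """Delegate to :meth:`invoke_service`, recording usage statistics."""
        stats = self._stats.setdefault(service_id, {"calls": 0, "errors": 0, "cards": 0})
        stats["calls"] += 1
        try:
            cards = self.invoke_service(service_id, request)
        except Exception:
            stats["errors"] += 1
            raise
        stats["cards"] += len(cards)
        return cards

    def stats(self) -> dict:
        return {sid: dict(counters) for sid, counters in sorted(self._stats.items())}

    # -- events, health, logs ----------------------------------------------

    def post_event(self, event: dict) -> None:
        self.event_log.append(
            {"received_at": dt.datetime.now(dt.timezone.utc).isoformat(), **event}
        )

    def add_health_check(self, name: str, fn) -> None:
        """Register a check: ``fn() -> (CheckStatus, detail)``."""
        self._health_checks.append((name, fn))

    def health_check(self) -> HealthStatus:
        """Built-in checks (store reachability, host disk space, catalog
        integrity) plus any registered application checks; worst-of wins."""
        checks = [self._check_store(), self._check_disk(), self._check_catalog()]
        for name, fn in self._health_checks:
            try:
                status, detail = fn()
                checks.append(HealthCheck(name, status, detail))
            except Exception as exc:
                checks.append(HealthCheck(name, CheckStatus.FAIL, str(exc)))
        return HealthStatus(checks)

    def _check_store(self) -> HealthCheck:
        root = self.store.root
        if root is None:
            return HealthCheck("store", CheckStatus.PASS, "in-memory store")
        if root.is_dir():
            return HealthCheck("store", CheckStatus.PASS, str(root))
        return HealthCheck("store", CheckStatus.FAIL, f"store root missing: {root}")

    def _check_disk(self, warn_below_mb: int = 512, fail_below_mb: int = 64) -> HealthCheck:
        target = str(self.store.root) if self.store.root and self.store.root.is_dir() else "."
        usage = shutil.disk_usage(target)
        free_mb = usage.free / 1e6
        if free_mb < fail_below_mb:
            return HealthCheck("disk-space", CheckStatus.FAIL, f"{free_mb:.0f} MB free")
        if free_mb < warn_below_mb:
            return HealthCheck("disk-space", CheckStatus.WARN, f"{free_mb:.0f} MB free")
        return HealthCheck("disk-space", CheckStatus.PASS, f"{free_mb:.0f} MB free")

    def _check_catalog(self) -> HealthCheck:
        broken = []
        for sid in sorted(self._services):
            d = self._services[sid]
            try:
                self.store.get_entity(d.engine_kind, d.engine_id)
            except Exception:
                broken.append(sid)
        if broken:
            return HealthCheck(
                "catalog", CheckStatus.FAIL, "unresolvable bindings: " + ", ".join(broken)
            )
        return HealthCheck("catalog", CheckStatus.PASS, f"{len(self._services)} services")

    def _record(self, transaction_id, service_id, outcome, started, cards=None, error=None):
        self.transaction_log.append(
            TransactionLogEntry(
                transaction_id=transaction_id,
                timestamp=dt.datetime.now(dt.timezone.utc).isoformat(),
                service_id=service_id,
                outcome=outcome,
                duration_ms=(time.perf_counter() - started) * 1000.0,
                error=error,
            )
        )
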