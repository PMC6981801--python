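"""CDS Hooks 1.0 protocol objects: service descriptors, requests, cards,
plus the platform-side health and transaction-log records."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from ..errors import ParseError

#: Hooks with first-class support; any other non-empty string is accepted
#: as a custom hook.
WELL_KNOWN_HOOKS = ("patient-view", "order-select", "order-sign")


@dataclass(frozen=True)
class CDSServiceDescriptor:
    """Catalog entry binding a hook to a knowledge-base engine.

    ``engine_kind`` is ``"rule_kb"`` or ``"bayes_model"``; ``engine_id``
    names the bound entity in the knowledge store.
    """

    service_id: str
    hook: str
    title: str
    description: str
    engine_kind: str
    engine_id: str
    prefetch: tuple[tuple[str, str], ...] = ()  # token -> FHIR query template

    def __post_init__(self):
        if not self.service_id:
            raise ValueError("service_id must be non-empty")
        if not self.hook:
            raise ValueError("hook must be non-empty")

    def to_discovery(self) -> dict:
        out = {
            "id": self.service_id,
            "hook": self.hook,
            "title": self.title,
            "description": self.description,
        }
        if self.prefetch:
            out["prefetch"] = dict(self.prefetch)
        return out


@dataclass
class CDSRequest:
    hook: str
    hook_instance: str
    context: dict
    prefetch: dict = field(default_factory=dict)
    fhir_server: str | None = None

    @classmethod
    def from_dict(cls, body: dict) -> "CDSRequest":
        if not isinstance(body, dict):
            raise ParseError("request body must be a JSON object")
        hook = body.get("hook")
        instance = body.get("hookInstance")
        if not hook or not isinstance(hook, str):
            raise ParseError("request is missing 'hook'")
        if not instance or not isinstance(instance, str):
            raise ParseError("request is missing 'hookInstance'")
        context = body.get("context") or {}
        if not isinstance(context, dict):
            raise ParseError("'context' must be an object")
        prefetch = body.get("prefetch") or {}
        if not isinstance(prefetch, dict):
            raise ParseError("'prefetch' must be an object")
        return cls(
            hook=hook,
            hook_instance=instance,
            context=context,
            prefetch=prefetch,
            fhir_server=body.get("fhirServer"),
        )

    @property
    def patient_id(self) -> str | None:
        return self.context.get("patientId")


class Indicator(str, enum.Enum):
    INFO = "info"
    WARNING = "warning"
    CRITICAL = "critical"


@dataclass(frozen=True)
class Suggestion:
    label: str

    def to_dict(self) -> dict:
        return {"label": self.label}


@dataclass(frozen=True)
class Card:
    summary: str
    indicator: Indicator
    source_label: str
    detail: str | None = None
    source_url: str | None = None
    suggestions: tuple[Suggestion, ...] = ()

    def __post_init__(self):
        if not self.summary:
            raise ValueError("card summary must be non-empty")
        if len(self.summary) > 140:
            raise ValueError("card summary must be at most 140 characters")

    def to_dict(self) -> dict:
        source = {"label": self.source_label}
        if self.source_url:
            source["url"] = self.source_url
        out = {
            "summary": self.summary,
            "indicator": self.indicator.value,
            "source": source,
        }
        if self.detail is not None:
            out["detail"] = self.detail
        if self.suggestions:
            out["suggestions"] = [s.to_dict() for s in self.suggestions]
        return out


class CheckStatus(str, enum.Enum):
    PASS = "pass"
    WARN = "warn"
    FAIL = "fail"


_SEVERITY = {CheckStatus.PASS: 0, CheckStatus.WARN: 1, CheckStatus.FAIL: 2}


@dataclass(frozen=True)
class HealthCheck:
    name: str
    status: CheckStatus
    detail: str = ""


@dataclass
class HealthStatus:
    checks: list[HealthCheck]

    @property
    def status(self) -> CheckStatus:
        """Overall status is the worst individual check status."""
        if not self.checks:
            return CheckStatus.PASS
        return max((c.status for c in self.checks), key=_SEVERITY.__getitem__)

    def to_dict(self) -> dict:
        return {
            "status": self.status.value,
            "checks": [
                {"name": c.name, "status": c.status.value, "detail": c.detail}
                for c in self.checks
            ],
        }


@dataclass(frozen=True)
class TransactionLogEntry:
    transaction_id: str
    timestamp: str
    service_id: str
    outcome: str  # "ok" | "error"
    duration_ms: float
    error: str | None = None
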