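"""Typed exceptions shared across the engine modules."""


class FhirCdsError(Exception):
    """Base class for all package errors."""


class ParseError(FhirCdsError):
    """Malformed input document (JSON/YAML syntax or shape)."""


class UnsupportedResourceError(FhirCdsError):
    """Resource type outside the supported FHIR R4 set."""

    def __init__(self, resource_type: str):
        self.resource_type = resource_type
        super().__init__(f"unsupported FHIR resource type: {resource_type!r}")


class AdapterError(FhirCdsError):
    """Bundle-to-facts conversion failure (bad Patient cardinality, invalid entry)."""


class KnowledgeBaseError(FhirCdsError):
    """Knowledge-base integrity failure; carries the validation report."""

    def __init__(self, message, report=None):
        self.report = report
        super().__init__(message)


class EvaluationError(FhirCdsError):
    """Rule evaluation failure (e.g., an unresolved condition-tree leaf)."""


class InconsistentEvidenceError(FhirCdsError):
    """Evidence with probability zero under the Bayesian model."""


class ConflictingEvidenceError(FhirCdsError):
    """A node re-assigned to a different observed state within one session."""


class StoreConflictError(FhirCdsError):
    """Stale-version write against the knowledge store."""


class NotFoundError(FhirCdsError):
    """Unknown entity id / version / service id."""


class ModelNotAcceptedError(FhirCdsError):
    """Bayesian model lacking two-expert consensus bound to a production service."""
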