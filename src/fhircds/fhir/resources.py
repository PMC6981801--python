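"""Minimal FHIR R4 resource model: parse, serialize, validate.

The platform reads only a handful of fields from each resource; everything
else round-trips untouched. A :class:`FhirResource` therefore wraps the raw
JSON tree rather than projecting it onto a closed schema — serialization
then parsing yields a structurally identical document, including unknown
extension fields (forward compatibility).

Only the FHIR R4 JSON dialect is accepted; XML input is rejected with a
clear error.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

from ..errors import ParseError, UnsupportedResourceError

#: Clinical resource types the platform exchanges, plus Patient (the main
#: resource), Bundle (the batch container) and ServiceRequest (emitted for
#: referral / procedure / lab-test recommendations).
SUPPORTED_RESOURCE_TYPES: frozenset[str] = frozenset(
    {
        "CarePlan",
        "MedicationRequest",
        "ActivityDefinition",
        "DetectedIssue",
        "RiskAssessment",
        "Questionnaire",
        "QuestionnaireResponse",
        "ResearchDefinition",
        "PlanDefinition",
        "Goal",
        "Observation",
        "Condition",
        "FamilyMemberHistory",
        "DiagnosticReport",
        "Group",
        "RequestGroup",
        "AllergyIntolerance",
        "Immunization",
        "Procedure",
        "Encounter",
        "Appointment",
        "Patient",
        "Bundle",
        "ServiceRequest",
    }
)


class Severity(str, enum.Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class ValidationIssue:
    severity: Severity
    path: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(i.severity is Severity.ERROR for i in self.issues)

    def error(self, path: str, message: str) -> None:
        self.issues.append(ValidationIssue(Severity.ERROR, path, message))

    def warning(self, path: str, message: str) -> None:
        self.issues.append(ValidationIssue(Severity.WARNING, path, message))

    def extend(self, other: "ValidationReport", prefix: str = "") -> None:
        for i in other.issues:
            path = f"{prefix}{i.path}" if prefix else i.path
            self.issues.append(ValidationIssue(i.severity, path, i.message))

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity is Severity.ERROR]

    def as_dict(self) -> dict:
        return {
            "valid": self.valid,
            "issues": [
                {"severity": i.severity.value, "path": i.path, "message": i.message}
                for i in self.issues
            ],
        }


@dataclass(frozen=True)
class FhirResource:
    """A supported FHIR R4 resource wrapping its raw JSON content.

    ``content`` always contains ``resourceType``; equality is structural
    equality of the content tree.
    """

    resource_type: str
    id: str | None
    content: dict

    def __eq__(self, other):
        if not isinstance(other, FhirResource):
            return NotImplemented
        return self.content == other.content

    def __hash__(self):
        return hash((self.resource_type, self.id))

    def get(self, path: str, default=None):
        """Dotted-path field access, e.g. ``get("code.coding")``."""
        node = self.content
        for part in path.split("."):
            if not isinstance(node, dict) or part not in node:
                return default
            node = node[part]
        return node


def parse_resource(json_document: str | bytes | dict) -> FhirResource:
    """Parse a FHIR R4 JSON document into a :class:`FhirResource`.

    Accepts raw JSON text (or an already-decoded dict for convenience).
    Unknown fields are preserved verbatim in ``content``.
    """
    if isinstance(json_document, dict):
        doc = json_document
    else:
        if isinstance(json_document, bytes):
            json_document = json_document.decode("utf-8")
        stripped = json_document.lstrip()
        if stripped.startswith("<"):
            raise ParseError("XML input is not supported; supply FHIR R4 JSON")
        try:
            doc = json.loads(json_document)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError("a FHIR resource must be a JSON object")
    rtype = doc.get("resourceType")
    if not rtype:
        raise UnsupportedResourceError("<missing resourceType>")
    if rtype not in SUPPORTED_RESOURCE_TYPES:
        raise UnsupportedResourceError(rtype)
    return FhirResource(resource_type=rtype, id=doc.get("id"), content=doc)


def serialize_resource(resource: FhirResource) -> str:
    """Emit FHIR-R4-shaped JSON; inverse of :func:`parse_resource`."""
    if resource.resource_type not in SUPPORTED_RESOURCE_TYPES:
        raise UnsupportedResourceError(resource.resource_type)
    return json.dumps(resource.content, ensure_ascii=False, sort_keys=True)


# Per-type profile constraints: only the fields the engines read are checked.
_MANDATORY: dict[str, tuple[str, ...]] = {
    "Observation": ("code", "subject"),
    "Condition": ("code", "subject"),
    "AllergyIntolerance": ("code", "patient"),
    "Procedure": ("code", "subject"),
    "Immunization": ("vaccineCode", "patient"),
    "DiagnosticReport": ("code", "subject"),
}

_OBSERVATION_VALUE_KEYS = (
    "valueQuantity",
    "valueCodeableConcept",
    "valueBoolean",
    "valueString",
    "valueInteger",
)


def validate_resource(resource: FhirResource) -> ValidationReport:
    """Check a resource against the platform's profile of its type.

    Missing mandatory fields are errors; present-but-unusable fields
    (e.g. a quantity without a unit) are warnings. Patient carries no
    clinical payload, so a bare Patient is valid.
    """
    report = ValidationReport()
    content = resource.content
    for fld in _MANDATORY.get(resource.resource_type, ()):
        if fld not in content:
            report.error(fld, f"{resource.resource_type} requires {fld}")
    if resource.resource_type == "Observation":
        _validate_observation(content, report)
    if resource.resource_type == "Bundle":
        for i, entry in enumerate(content.get("entry", [])):
            if "resource" not in entry:
                report.error(f"entry[{i}]", "Bundle entry without a resource")
    return report


def _validate_observation(content: dict, report: ValidationReport) -> None:
    code = content.get("code")
    if isinstance(code, dict) and not code.get("coding"):
        report.warning("code.coding", "Observation code has no coding entries")
    vq = content.get("valueQuantity")
    if isinstance(vq, dict):
        if "value" not in vq:
            report.error("valueQuantity.value", "quantity without a value")
        elif not vq.get("unit") and not vq.get("code"):
            report.warning("valueQuantity.unit", "quantity without a unit")
    has_value = any(k in content for k in _OBSERVATION_VALUE_KEYS)
    if not has_value and "component" not in content:
        report.warning("value[x]", "Observation carries no value and no components")
    for i, comp in enumerate(content.get("component", [])):
        if "code" not in comp:
            report.error(f"component[{i}].code", "component without a code")
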