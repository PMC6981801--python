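"""FHIR Adapter: bundles to internal facts, inference results back to FHIR.

The adapter is the boundary between the interoperability layer and the
inference engines. Incoming bundles are validated, then flattened into a
set of :class:`~fhircds.facts.Fact`; outgoing inference results become a
``DiagnosticReport`` whose conclusion and contained entries carry the fired
artifacts.
"""

from __future__ import annotations

import datetime as dt

from ..errors import AdapterError
from ..facts import Fact, FactStatus, Quantity
from ..terminology import CodedConcept
from .resources import FhirResource, parse_resource, validate_resource

#: Resource types flattened into boolean presence facts keyed by their code.
_PRESENCE_TYPES = {
    "Condition": ("code", "subject"),
    "AllergyIntolerance": ("code", "patient"),
    "Procedure": ("code", "subject"),
    "Immunization": ("vaccineCode", "patient"),
}

_STATUS_MAP = {
    "final": FactStatus.FINAL,
    "preliminary": FactStatus.PRELIMINARY,
    "amended": FactStatus.AMENDED,
    "corrected": FactStatus.AMENDED,
    "entered-in-error": FactStatus.ENTERED_IN_ERROR,
}


def _first_concept(codeable: dict | None) -> CodedConcept | None:
    if not isinstance(codeable, dict):
        return None
    for coding in codeable.get("coding", []):
        if coding.get("system") and coding.get("code"):
            return CodedConcept.from_fhir(coding)
    return None


def _parse_time(value: str | None) -> dt.datetime | None:
    if not value:
        return None
    try:
        return dt.datetime.fromisoformat(value.replace("Z", "+00:00"))
    except ValueError:
        return None


def extract_facts(
    bundle: FhirResource, received_at: dt.datetime | None = None
) -> set[Fact]:
    """Flatten a Bundle into the fact set the engines consume.

    The bundle must contain exactly one Patient; all facts share its id.
    Entered-in-error entries contribute nothing. Effective time is taken
    from ``effectiveDateTime``, else ``issued``, else the bundle's
    ``timestamp``, else ``received_at`` (defaulting to the current time) —
    in that precedence order.
    """
    if bundle.resource_type != "Bundle":
        raise AdapterError(f"expected a Bundle, got {bundle.resource_type}")
    entries = [
        parse_resource(e["resource"])
        for e in bundle.content.get("entry", [])
        if "resource" in e
    ]
    patients = [r for r in entries if r.resource_type == "Patient"]
    if len(patients) != 1:
        raise AdapterError(f"bundle must contain exactly one Patient, found {len(patients)}")
    subject_id = patients[0].id or "unknown"

    fallback = (
        _parse_time(bundle.content.get("timestamp"))
        or received_at
        or dt.datetime.now(dt.timezone.utc)
    )

    facts: set[Fact] = set()
    for idx, res in enumerate(entries):
        if res.resource_type == "Patient":
            continue
        report = validate_resource(res)
        if not report.valid:
            first = report.errors()[0]
            raise AdapterError(
                f"bundle entry {idx} ({res.resource_type}/{res.id}) invalid: "
                f"{first.path}: {first.message}"
            )
        if res.resource_type == "Observation":
            facts.update(_observation_facts(res, subject_id, fallback))
        elif res.resource_type in _PRESENCE_TYPES:
            fact = _presence_fact(res, subject_id, fallback)
            if fact is not None:
                facts.add(fact)
        # Remaining supported types (Group, RequestGroup, CarePlan, ...)
        # validate and round-trip but contribute no facts.
    return {f for f in facts if f.is_usable}


def _fact_status(content: dict) -> FactStatus:
    return _STATUS_MAP.get(content.get("status", "final"), FactStatus.FINAL)


def _value_from(content: dict):
    """Map a FHIR value[x] choice onto the internal fact value union."""
    if "valueQuantity" in content:
        vq = content["valueQuantity"]
        return Quantity(float(vq["value"]), vq.get("unit", vq.get("code", "")) or "")
    if "valueInteger" in content:
        return Quantity(float(content["valueInteger"]), "")
    if "valueCodeableConcept" in content:
        return _first_concept(content["valueCodeableConcept"])
    if "valueBoolean" in content:
        return bool(content["valueBoolean"])
    if "valueString" in content:
        return str(content["valueString"])
    return None


def _observation_facts(
    res: FhirResource, subject_id: str, fallback: dt.datetime
) -> list[Fact]:
    content = res.content
    status = _fact_status(content)
    when = (
        _parse_time(content.get("effectiveDateTime"))
        or _parse_time(content.get("issued"))
        or fallback
    )
    out: list[Fact] = []
    concept = _first_concept(content.get("code"))
    value = _value_from(content)
    if concept is not None and value is not None:
        out.append(Fact(subject_id, concept, value, when, status))
    # Each component becomes its own fact (e.g. systolic/diastolic pressure).
    for comp in content.get("component", []):
        c = _first_concept(comp.get("code"))
        v = _value_from(comp)
        if c is not None and v is not None:
            out.append(Fact(subject_id, c, v, when, status))
    return out


def _presence_fact(
    res: FhirResource, subject_id: str, fallback: dt.datetime
) -> Fact | None:
    code_field = _PRESENCE_TYPES[res.resource_type][0]
    concept = _first_concept(res.content.get(code_field))
    if concept is None:
        return None
    verification = res.content.get("verificationStatus")
    if isinstance(verification, dict):
        codes = {c.get("code") for c in verification.get("coding", [])}
        if "entered-in-error" in codes:
            return None
    when = (
        _parse_time(res.content.get("recordedDate"))
        or _parse_time(res.content.get("performedDateTime"))
        or _parse_time(res.content.get("occurrenceDateTime"))
        or fallback
    )
    return Fact(subject_id, concept, True, when, _fact_status(res.content))


# Artifact types mapped to contained resources of the emitted report.
_CONTAINED_MAPPING = {
    "Risk": "RiskAssessment",
    "ReferralRequest": "ServiceRequest",
    "ProcedureRequest": "ServiceRequest",
    "DiagnosticRequest": "ServiceRequest",
}

_NO_FINDINGS_CODE = {
    "coding": [
        {"system": "urn:fhircds:status", "code": "no-findings", "display": "No findings"}
    ]
}


def emit_diagnostic_report(result, patient_id: str) -> FhirResource:
    """Render an inference result as a FHIR DiagnosticReport.

    The conclusion concatenates the fired artifacts' texts in firing order;
    artifact concepts become ``conclusionCode`` entries; Risk artifacts are
    contained as RiskAssessment and the three request artifact types as
    ServiceRequest. An empty result yields a report with an empty
    conclusion and a "no findings" coded status — not an error.
    """
    artifacts = list(result.fired_artifacts)
    contained: list[dict] = []
    conclusion_codes: list[dict] = []
    texts: list[str] = []
    for i, art in enumerate(artifacts):
        if art.text:
            texts.append(art.text)
        if art.concept is not None:
            conclusion_codes.append({"coding": [art.concept.to_fhir()]})
        target = _CONTAINED_MAPPING.get(art.type.value)
        if target == "RiskAssessment":
            contained.append(
                {
                    "resourceType": "RiskAssessment",
                    "id": f"risk-{i}",
                    "status": "final",
                    "subject": {"reference": f"Patient/{patient_id}"},
                    "prediction": [{"outcome": {"text": art.text}}],
                }
            )
        elif target == "ServiceRequest":
            contained.append(
                {
                    "resourceType": "ServiceRequest",
                    "id": f"request-{i}",
                    "status": "draft",
                    "intent": "proposal",
                    "subject": {"reference": f"Patient/{patient_id}"},
                    "code": {"text": art.text},
                }
            )
    content: dict = {
        "resourceType": "DiagnosticReport",
        "id": f"report-{result.transaction_id}",
        "status": "final",
        "code": {
            "coding": [
                {
                    "system": "urn:fhircds:report",
                    "code": "decision-support",
                    "display": "Clinical decision support report",
                }
            ]
        },
        "subject": {"reference": f"Patient/{patient_id}"},
        "conclusion": "\n".join(texts),
    }
    if conclusion_codes:
        content["conclusionCode"] = conclusion_codes
    if contained:
        content["contained"] = contained
    if not artifacts:
        content["conclusionCode"] = [_NO_FINDINGS_CODE]
    return FhirResource("DiagnosticReport", content["id"], content)
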