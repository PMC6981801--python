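"""Synthetic patient bundles.

Stands in for HIS-supplied patient data: one Patient plus coded
Observations with values, units and timestamps, drawn from a declared
concept pool. Values are sampled inside each concept's reference interval
or — with probability ``abnormal_fraction`` — outside it, so rule
thresholds keyed to those intervals have a known firing probability.

Everything is seed-deterministic: the same spec yields byte-identical
bundle JSON.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from ..fhir.resources import FhirResource, parse_resource
from ..terminology import LOINC, CodedConcept


@dataclass(frozen=True)
class ConceptSpec:
    """One observable concept with its unit and reference interval."""

    concept: CodedConcept
    unit: str
    low: float
    high: float
    #: Spread used when sampling outside the interval.
    abnormal_span: float = 0.5


#: Common laboratory/vital concepts with plausible adult reference intervals.
DEFAULT_CONCEPT_POOL: tuple[ConceptSpec, ...] = (
    ConceptSpec(CodedConcept(LOINC, "2345-7", "Glucose [Moles/volume] in Serum or Plasma"),
                "mmol/L", 3.9, 5.5),
    ConceptSpec(CodedConcept(LOINC, "718-7", "Hemoglobin [Mass/volume] in Blood"),
                "g/L", 120.0, 160.0),
    ConceptSpec(CodedConcept(LOINC, "2276-4", "Ferritin [Mass/volume] in Serum or Plasma"),
                "ug/L", 30.0, 300.0),
    ConceptSpec(CodedConcept(LOINC, "6690-2", "Leukocytes [#/volume] in Blood"),
                "10*9/L", 4.0, 9.0),
    ConceptSpec(CodedConcept(LOINC, "1742-6", "Alanine aminotransferase [Enzymatic activity/volume]"),
                "U/L", 7.0, 45.0),
    ConceptSpec(CodedConcept(LOINC, "1975-2", "Bilirubin.total [Mass/volume] in Serum or Plasma"),
                "umol/L", 3.0, 21.0),
    ConceptSpec(CodedConcept(LOINC, "2324-2", "Gamma glutamyl transferase [Enzymatic activity/volume]"),
                "U/L", 9.0, 48.0),
    ConceptSpec(CodedConcept(LOINC, "3094-0", "Urea nitrogen [Mass/volume] in Serum or Plasma"),
                "mmol/L", 2.5, 7.1),
    ConceptSpec(CodedConcept(LOINC, "2160-0", "Creatinine [Mass/volume] in Serum or Plasma"),
                "umol/L", 60.0, 110.0),
    ConceptSpec(CodedConcept(LOINC, "39156-5", "Body mass index (BMI) [Ratio]"),
                "kg/m2", 18.5, 25.0),
    ConceptSpec(CodedConcept(LOINC, "8310-5", "Body temperature"),
                "Cel", 36.1, 37.2),
    ConceptSpec(CodedConcept(LOINC, "3024-7", "Thyroxine (T4) free [Mass/volume] in Serum or Plasma"),
                "pmol/L", 12.0, 22.0),
)


@dataclass(frozen=True)
class PatientSpec:
    """Deterministic recipe for one synthetic patient bundle."""

    seed: int
    n_observations: int = 10
    concept_pool: tuple[ConceptSpec, ...] = DEFAULT_CONCEPT_POOL
    abnormal_fraction: float = 0.2
    #: Side of the reference interval abnormal values fall on.
    abnormal_direction: str = "both"  # "high" | "low" | "both"
    patient_id: str | None = None
    base_time: str = "2024-01-15T09:00:00+00:00"

    def __post_init__(self):
        if not 0.0 <= self.abnormal_fraction <= 1.0:
            raise ValueError("abnormal_fraction must lie in [0, 1]")
        if self.n_observations < 0:
            raise ValueError("n_observations must be non-negative")


def generate_patient_bundle(spec: PatientSpec) -> FhirResource:
    """Generate a Bundle of one Patient plus ``n_observations`` Observations.

    Each observation draws a concept from the pool (round-robin so every
    concept appears before any repeats) and a value uniformly inside its
    reference interval, or outside it (above or below, half-and-half) with
    probability ``abnormal_fraction``.
    """
    rng = random.Random(spec.seed)
    pid = spec.patient_id or f"patient-{spec.seed}"
    entries: list[dict] = [
        {
            "resource": {
                "resourceType": "Patient",
                "id": pid,
                "gender": rng.choice(["female", "male"]),
                "birthDate": f"{rng.randint(1940, 2005)}-{rng.randint(1, 12):02d}-15",
            }
        }
    ]
    for i in range(spec.n_observations):
        cs = spec.concept_pool[i % len(spec.concept_pool)]
        abnormal = rng.random() < spec.abnormal_fraction
        span = (cs.high - cs.low) * cs.abnormal_span
        if abnormal:
            direction = spec.abnormal_direction
            if direction == "both":
                direction = "high" if rng.random() < 0.5 else "low"
            if direction == "high":
                value = rng.uniform(cs.high + 0.001 * span, cs.high + span)
            else:
                value = rng.uniform(max(0.0, cs.low - span), cs.low - 0.001 * span)
        else:
            value = rng.uniform(cs.low, cs.high)
        # minutes offset keeps timestamps distinct and deterministic
        hour, minute = divmod(i, 60)
        entries.append(
            {
                "resource": {
                    "resourceType": "Observation",
                    "id": f"obs-{spec.seed}-{i}",
                    "status": "final",
                    "code": {"coding": [cs.concept.to_fhir()]},
                    "subject": {"reference": f"Patient/{pid}"},
                    "effectiveDateTime": _offset(spec.base_time, hour, minute),
                    "valueQuantity": {
                        "value": round(value, 3),
                        "unit": cs.unit,
                        "system": "http://unitsofmeasure.org",
                        "code": cs.unit,
                    },
                }
            }
        )
    bundle = {
        "resourceType": "Bundle",
        "id": f"bundle-{spec.seed}",
        "type": "collection",
        "timestamp": spec.base_time,
        "entry": entries,
    }
    return parse_resource(bundle)


def _offset(base_iso: str, hours: int, minutes: int) -> str:
    import datetime as dt

    base = dt.datetime.fromisoformat(base_iso)
    return (base + dt.timedelta(hours=hours, minutes=minutes)).isoformat()


def generate_resource_corpus(seed: int, n: int) -> list[FhirResource]:
    """``n`` synthetic resources cycling through every supported type.

    Each resource gets its type's minimal payload plus randomized extra
    fields — including an unrecognized extension-like field — so
    round-trip tests exercise the lossless-passthrough contract, not just
    the fields the platform reads.
    """
    from ..fhir.resources import SUPPORTED_RESOURCE_TYPES

    rng = random.Random(seed)
    types = sorted(SUPPORTED_RESOURCE_TYPES)
    out: list[FhirResource] = []
    for i in range(n):
        rtype = types[i % len(types)]
        doc: dict = {"resourceType": rtype, "id": f"{rtype.lower()}-{seed}-{i}"}
        if rtype == "Observation":
            doc.update(
                {
                    "status": "final",
                    "code": {"coding": [{"system": LOINC, "code": f"{rng.randint(1000, 9999)}-0"}]},
                    "subject": {"reference": f"Patient/p{i}"},
                    "valueQuantity": {"value": round(rng.uniform(0, 100), 2), "unit": "u"},
                }
            )
        elif rtype in ("Condition", "Procedure"):
            doc.update(
                {
                    "code": {"coding": [{"system": "http://snomed.info/sct",
                                         "code": str(rng.randint(10**6, 10**7))}]},
                    "subject": {"reference": f"Patient/p{i}"},
                }
            )
        elif rtype == "AllergyIntolerance":
            doc.update(
                {
                    "code": {"coding": [{"system": "http://snomed.info/sct",
                                         "code": str(rng.randint(10**6, 10**7))}]},
                    "patient": {"reference": f"Patient/p{i}"},
                }
            )
        elif rtype == "Immunization":
            doc.update(
                {
                    "vaccineCode": {"coding": [{"system": "http://snomed.info/sct",
                                                "code": str(rng.randint(10**6, 10**7))}]},
                    "patient": {"reference": f"Patient/p{i}"},
                    "status": "completed",
                }
            )
        elif rtype == "DiagnosticReport":
            doc.update(
                {
                    "status": "final",
                    "code": {"text": "panel"},
                    "subject": {"reference": f"Patient/p{i}"},
                }
            )
        elif rtype == "Bundle":
            doc.update({"type": "collection", "entry": []})
        # unknown fields must survive serialization untouched
        doc["extension"] = [
            {"url": f"urn:fhircds:test:{rng.randint(0, 999)}", "valueInteger": rng.randint(0, 10**6)}
        ]
        if rng.random() < 0.5:
            doc["_unrecognizedField"] = {"nested": [rng.random(), "text", None]}
        out.append(parse_resource(doc))
    return out
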