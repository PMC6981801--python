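"""Coded concepts and the terminology-system registry.

Every fact, rule, and Bayesian-network node carries a :class:`CodedConcept` —
a code qualified by the URI of the terminology system it belongs to (LOINC
for lab observations, SNOMED CT for clinical concepts, ICD-10 for disease
classification). Identity is the ``(system, code)`` pair; the human-readable
``display`` never participates in equality or hashing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

LOINC = "http://loinc.org"
SNOMED_CT = "http://snomed.info/sct"
ICD10 = "http://hl7.org/fhir/sid/icd-10"
#: Namespace for illustrative demo codes that are not real LOINC/SNOMED content.
DEMO = "urn:fhircds:demo"

_KNOWN_SYSTEMS = {LOINC, SNOMED_CT, ICD10, DEMO}


class TerminologyRegistry:
    """Static registry of known code-system URIs, optionally with code lists.

    Realizes the platform's terminology service as an in-process lookup:
    known system URIs plus optional per-system code sets loaded from plain
    files. No external terminology server is contacted.
    """

    def __init__(self, extra_systems: set[str] | None = None):
        self._systems = set(_KNOWN_SYSTEMS)
        if extra_systems:
            self._systems |= set(extra_systems)
        self._code_lists: dict[str, set[str]] = {}

    def register_system(self, uri: str) -> None:
        self._systems.add(uri)

    def load_code_list(self, system: str, codes) -> None:
        """Attach an explicit code list to a system; lookups then check membership."""
        self.register_system(system)
        self._code_lists[system] = set(codes)

    def knows_system(self, uri: str) -> bool:
        return uri in self._systems

    def knows_code(self, concept: "CodedConcept") -> bool:
        if concept.system not in self._systems:
            return False
        codes = self._code_lists.get(concept.system)
        return True if codes is None else concept.code in codes


#: Process-wide default registry; modules accept an explicit one where it matters.
DEFAULT_REGISTRY = TerminologyRegistry()


@dataclass(frozen=True)
class CodedConcept:
    """A terminology-system-qualified code.

    Equality and hashing use ``(system, code)`` only.
    """

    system: str
    code: str
    display: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.code:
            raise ValueError("CodedConcept.code must be non-empty")
        if not self.system:
            raise ValueError("CodedConcept.system must be non-empty")

    def to_fhir(self) -> dict:
        """Render as a FHIR ``Coding`` object."""
        out = {"system": self.system, "code": self.code}
        if self.display is not None:
            out["display"] = self.display
        return out

    @classmethod
    def from_fhir(cls, coding: dict) -> "CodedConcept":
        return cls(
            system=coding.get("system", ""),
            code=coding.get("code", ""),
            display=coding.get("display"),
        )

    def as_dict(self) -> dict:
        out = {"system": self.system, "code": self.code}
        if self.display is not None:
            out["display"] = self.display
        return out
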