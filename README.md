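# fhircds

A clinical decision support (CDS) platform core over FHIR R4: a
production-rule engine with three-valued logic for laboratory
interpretation and risk assessment, an exact Bayesian diagnostic-network
engine, a versioned knowledge store, and a CDS Hooks 1.0 service facade —
all in pure Python with deterministic, auditable behavior.

**All packaged clinical content is illustrative teaching material, not
clinical guidance.** Every demo knowledge base carries that provenance in
its metadata, and the CDS layer surfaces it on every card.

## What it does

Hospital information systems hold patient data as FHIR resources
(Patient, Observation, Condition, …) coded in standard terminologies
(LOINC, SNOMED CT, ICD-10). Decision support means turning a bundle of
such resources into typed conclusions — risk flags, candidate diagnoses,
recommendations, requests for further testing — delivered back into the
clinical workflow as CDS Hooks cards or FHIR DiagnosticReports.

The platform supports two complementary knowledge representations:

- **Production rules.** Atomic *operation rules* compare a coded
  measurement against a threshold or range (`GT`, `GE`, `LT`, `LE`, `EQ`,
  `NE`, `IN_RANGE`, `EXISTS`); *aggregate rules* combine them with
  AND/OR/NOT trees and conclude typed *artifacts* (Scale, Risk, Diagnosis,
  Recommendation, referral/procedure/test requests, …). Evaluation uses
  strong Kleene three-valued logic: a missing or unit-mismatched
  measurement is UNKNOWN, UNKNOWN propagates through the connectives
  (AND = min, OR = max, NOT = complement), and an artifact fires only on a
  definite TRUE. Missing data therefore never produces a false alarm and
  never silently counts as normal.
- **Bayesian diagnostic networks.** Directed acyclic graphs over
  discrete clinical variables (diagnoses, risk factors, symptoms, signs,
  labs), each node carrying an explicit conditional probability table.
  Inference is exact variable elimination, cross-checked against a
  full-joint enumeration oracle. Continuous measurements are stratified
  into node states via half-open intervals (a boundary value belongs to
  the upper stratum). Evidence can be entered sequentially — the result
  is provably independent of entry order — and a model can only be bound
  to a service after two distinct expert signoffs.

Around the engines sit a versioned YAML knowledge store (gapless immutable
versions, optimistic concurrency, audit log, concept-based search), a FHIR
adapter (lossless JSON round-trip, profile validation, bundle → facts,
inference result → DiagnosticReport), synthetic patient generators, and a
stdlib WSGI app exposing CDS Hooks discovery and invocation plus health
and usage-statistics endpoints.

## Worked example

Write the packaged demo knowledge base (interpretation rules for eleven
ICD-10 groups plus a type-2-diabetes risk rule set) and run it on a bundle
with an iron-deficiency pattern — hemoglobin 95 g/L (below 120) and
ferritin 8 µg/L (below 30):

```bash
fhircds fixtures demo-kb --out kb.yaml
fhircds rules run --kb kb.yaml --bundle anemia.json
```

```
# Decision support report for knowledge base demo-interpretation-kb

## Diagnosis

- Laboratory pattern consistent with Iron deficiency anemia (D50). Illustrative demo content, not clinical guidance.

---
Transaction: 694097ed50834aada54acf11a594849f
```

Both conjuncts of the D50 rule hold, so exactly that artifact fires; with
normal labs the report is empty, and with only one conjunct present the
other evaluates UNKNOWN or FALSE and nothing fires.

The same bundle pipeline feeds the Bayesian engine. Given a patient with
chills (SNOMED 43724002) and a body temperature of 39.1 °C — stratified to
the `fever` state — the packaged respiratory model ranks its two diagnosis
nodes:

```bash
fhircds fixtures demo-bn --out model.yaml
fhircds bayes infer --model model.yaml --bundle fever.json
```

```json
{
  "evidence": {
    "fever": "fever",
    "chill": "present"
  },
  "warnings": [],
  "ranking": [
    {
      "node": "ard",
      "probability": 0.798595
    },
    {
      "node": "pneumonia",
      "probability": 0.297468
    }
  ]
}
```

Fever and chills are common to both conditions, so the higher-prior acute
respiratory disease leads. Adding the pneumonia-specific findings
(right-sided chest pain on cough, rusty sputum) drives
P(pneumonia | findings) to 0.992.

As a CDS Hooks service the same engines answer over HTTP:

```bash
fhircds serve --store ./store --port 8080
# GET  /cds-services            -> {"services": [...]}
# POST /cds-services/<id>       -> {"cards": [...]}
# GET  /health, /stats          -> operational endpoints
```

## Library use

```python
from fhircds.fhir import parse_resource, extract_facts
from fhircds.fixtures import demo_rule_kb
from fhircds.rules import run_inference

bundle = parse_resource(open("anemia.json").read())
result = run_inference(demo_rule_kb(), extract_facts(bundle))
for artifact in result.fired_artifacts:
    print(artifact.type.value, "-", artifact.text)
```

## Testing

```bash
python -m pytest -q tests/
```

The suite covers FHIR round-trips and validation, exhaustive
strong-Kleene truth tables, rule-engine equivalence against an
independent naive evaluator, variable elimination against full-joint
enumeration, evidence order invariance, store versioning and concurrency,
CDS Hooks conformance, and the CLI.

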