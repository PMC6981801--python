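# Methods

This note records the models, conventions and numerical choices the
platform implements, the defaults it ships with, and the limits of the
synthetic data used to exercise it.

## Fact model and FHIR adapter

The engines do not consume FHIR directly. The adapter reduces a Bundle
(exactly one Patient plus clinical resources) to a set of immutable
*facts*: `(subject, coded concept, value, effective time, status)`.
Observation values become quantities with units (per-component facts for
multi-component observations); Condition, AllergyIntolerance, Procedure
and Immunization entries become boolean presence facts. Facts with status
`entered-in-error` are dropped. Effective time is resolved in precedence
order `effectiveDateTime` → `issued` → bundle `timestamp` → receipt time,
so a fact is never silently undated.

Parsing is lossless: unknown fields and extensions survive
`parse ∘ serialize` byte-for-byte (canonical JSON with sorted keys), which
is what the 500-resource round-trip check verifies. Validation is a
deliberately small profile — per-type mandatory elements (e.g.
Observation `code` and `subject`) as errors, data-quality findings
(quantity without unit, observation without value) as warnings — not a
full FHIR profile validator.

Before inference, facts pass a filter policy: per `(subject, concept)`
only the most recent usable fact survives, optionally restricted to a
recency window (default: unbounded; the tests exercise 30 days).

## Production rules under strong Kleene logic

An operation rule compares one concept's fact against a constant:
`GT`, `GE`, `LT`, `LE`, `EQ`, `NE`, `IN_RANGE` (closed interval), and
`EXISTS`. Its result is three-valued:

- TRUE / FALSE when a usable, unit-matching fact decides it;
- UNKNOWN when the fact is missing, non-numeric where a number is
  required, or carries a different unit (no unit conversion is attempted —
  a conservative choice that avoids wrong-by-conversion results);
- `EXISTS` alone is never UNKNOWN: presence is decidable from the fact
  set itself.

Aggregate conditions combine rule results with AND = min, OR = max,
NOT = 2 − v over FALSE(0) < UNKNOWN(1) < TRUE(2) — the strong Kleene
tables. An artifact fires only on definite TRUE. The acceptance suite
checks the connectives exhaustively over every tree shape up to depth 3
(3 936 shapes × 27 assignments) against literal truth tables, and checks
whole-engine behavior on 200 random knowledge bases against an
independent naive evaluator that works on the serialized forms.

Fired artifacts are deduplicated (first firing rule wins, by rule id) and
ordered by fixed artifact-type priority (Scale, Risk, Diagnosis,
DiagnosticReport, referral/procedure/diagnostic requests, Description,
Recommendation, BehaviorRecommendation), then rule id — making reports
byte-deterministic for a given fact set.

## Bayesian diagnostic networks

Models are DAGs over discrete nodes with explicit per-row CPTs (each row
names its parent-state combination, so authored tables are reviewable).
Structural validation checks acyclicity, parent resolution, row counts
(∏ parent state counts), row sums within 1e-9, and probability ranges;
an *accepted* status additionally requires two distinct expert signoffs
before a model can back a service.

Inference is exact variable elimination over dense numpy factors with a
greedy min-degree (minimum fill-in) elimination order. Correctness is
checked against a chain-rule enumeration of the full joint (feasible up
to 2^20 entries), with observed agreement ~1e-15, comfortably within the
1e-9 gate. Evidence with zero marginal probability raises a typed
inconsistency error rather than returning NaNs; the CDS layer converts it
to a warning card.

Sequential evidence entry uses immutable sessions: each update re-runs
exact inference on the accumulated evidence, so commutativity and
sequential/batch equivalence hold by construction and are verified over
all 3! entry orders. Re-asserting the same state is idempotent; asserting
a different state for an already-observed variable is a hard error, not a
silent overwrite.

Continuous measurements map to node states via half-open strata
`[low, high)`; a boundary value belongs to the upper stratum (38.0 °C is
`fever`). Values outside all strata are skipped with a warning rather
than guessed.

## Knowledge store

Entities (rule knowledge bases, Bayesian models) are stored as serialized
YAML, one file per version under `<root>/<kind>/<id>/<version>.yaml`, or
purely in memory. Versions are gapless and immutable; writes validate
first and support optimistic concurrency (`expected_version` mismatch is
a conflict). Every write appends an actor-stamped entry to
`audit.jsonl`. Unknown top-level keys in knowledge files are preserved on
round-trip and reported as warnings, mirroring the FHIR passthrough
contract.

## CDS Hooks facade

Discovery and invocation follow CDS Hooks 1.0: `GET /cds-services`
returns `{"services": [...]}`; `POST /cds-services/{id}` returns
`{"cards": [...]}` where each card has a ≤140-character summary
(truncated at a word boundary with an ellipsis, full text moved to
`detail`), an indicator, and a source. The artifact-to-card mapping is
fixed: Risk → `warning`; Diagnosis → `info` unless its payload marks it
urgent (→ `critical`); the three request types carry one suggestion;
everything else is `info`. Invocation is stateless per request; every
request gets a transaction id shared by its log records, and per-service
call/error/card counters feed `/stats`. Health is worst-of over store
reachability, free disk space (warn < 512 MB, fail < 64 MB) and catalog
binding resolution, plus pluggable checks.

## Synthetic data

Patient bundles are seed-deterministic: observations draw concepts
round-robin from a 12-analyte LOINC pool with adult reference intervals
and sample uniformly inside the interval, or outside it with a configured
abnormal fraction and direction. This gives rule thresholds a known
firing probability but is not clinically realistic — values are
independent across analytes and time, with no physiological correlation
or disease trajectories. Random rule knowledge bases (bounded-depth
condition trees) and random binary DAGs (≤3 parents per node, Dirichlet-
free normalized rows) are sized so the enumeration oracle stays cheap.
The demo content (eleven ICD-10 interpretation groups, the diabetes risk
set, the respiratory network) uses plausible teaching thresholds and
probabilities and is labeled as illustrative in its metadata.

## Open decisions and limitations

- No unit conversion: a unit mismatch yields UNKNOWN instead of a
  converted comparison. Safe, but strict about knowledge-base authoring.
- The FHIR profile checks cover what the engines consume, not full R4
  conformance; XML is rejected by design.
- Variable elimination materializes dense factors; models with very large
  cliques would need a different factor representation. The packaged and
  generated models are far below that regime.
- The acceptance problem sizes (200 rule instances, 100 DAGs ≤ 12 nodes,
  depth-3 exhaustive logic, 500 round-trip resources) are this package's
  own verification choices: large enough to exercise every code path and
  operator, small enough to run in seconds.
- The WSGI server (`fhircds serve`) is single-threaded `wsgiref` —
  adequate for development and testing, not a production deployment
  surface.
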