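"""Packaged demo knowledge: interpretation rule sets for eleven ICD-10
groups, a type-2-diabetes risk rule set, and a respiratory Bayesian model.

All content is **illustrative, not clinical guidance**: thresholds and
probabilities are plausible teaching values authored for these fixtures,
and every generated knowledge base carries that provenance in its
metadata, which the CDS layer surfaces into card sources.
"""

from __future__ import annotations

from ..bayes.model import (
    BayesianModel,
    BayesNode,
    CptRow,
    ModelValidation,
    NodeRole,
    Stratum,
    ValidationStatus,
)
from ..kb.rulebase import RuleKnowledgeBase
from ..rules.model import (
    AggregateRule,
    And,
    Artifact,
    ArtifactType,
    Definition,
    Leaf,
    Operation,
    OperationRule,
    Or,
)
from ..terminology import ICD10, LOINC, SNOMED_CT, CodedConcept

PROVENANCE = "Illustrative demo content, not clinical guidance"

#: The eleven ICD-10 groups the packaged interpretation rules cover.
ICD10_GROUPS: dict[str, str] = {
    "N30": "Cystitis",
    "N04": "Nephrotic syndrome",
    "N10": "Acute pyelonephritis",
    "K75": "Other inflammatory liver diseases",
    "K71": "Toxic liver disease",
    "K81": "Cholecystitis",
    "K85": "Acute pancreatitis",
    "E05": "Thyrotoxicosis",
    "D50": "Iron deficiency anemia",
    "D72": "Other disorders of white blood cells",
    "N41": "Inflammatory diseases of prostate",
}

# Shared analyte catalogue: LOINC code -> (display, unit)
_ANALYTES = {
    "5821-4": ("Leukocytes [#/area] in Urine sediment", "/HPF"),
    "13945-1": ("Erythrocytes [#/area] in Urine sediment", "/HPF"),
    "2888-6": ("Protein [Mass/volume] in Urine", "g/L"),
    "1751-7": ("Albumin [Mass/volume] in Serum or Plasma", "g/L"),
    "6690-2": ("Leukocytes [#/volume] in Blood", "10*9/L"),
    "1988-5": ("C reactive protein [Mass/volume] in Serum or Plasma", "mg/L"),
    "1742-6": ("Alanine aminotransferase [Enzymatic activity/volume]", "U/L"),
    "1920-8": ("Aspartate aminotransferase [Enzymatic activity/volume]", "U/L"),
    "1975-2": ("Bilirubin.total [Mass/volume] in Serum or Plasma", "umol/L"),
    "3040-3": ("Lipase [Enzymatic activity/volume] in Serum or Plasma", "U/L"),
    "1798-8": ("Amylase [Enzymatic activity/volume] in Serum or Plasma", "U/L"),
    "3016-3": ("Thyrotropin [Units/volume] in Serum or Plasma", "mIU/L"),
    "3024-7": ("Thyroxine (T4) free [Mass/volume] in Serum or Plasma", "pmol/L"),
    "718-7": ("Hemoglobin [Mass/volume] in Blood", "g/L"),
    "2276-4": ("Ferritin [Mass/volume] in Serum or Plasma", "ug/L"),
    "751-8": ("Neutrophils [#/volume] in Blood", "10*9/L"),
    "2857-1": ("Prostate specific Ag [Mass/volume] in Serum or Plasma", "ug/L"),
    "2345-7": ("Glucose [Moles/volume] in Serum or Plasma", "mmol/L"),
    "39156-5": ("Body mass index (BMI) [Ratio]", "kg/m2"),
    "30525-0": ("Age", "a"),
}

# Per ICD-10 group: ((loinc, operation, value), ...), combining operator.
_GROUP_RULES: dict[str, tuple[tuple[tuple[str, Operation, float], ...], str]] = {
    "N30": ((("5821-4", Operation.GT, 10.0), ("13945-1", Operation.GT, 3.0)), "and"),
    "N04": ((("2888-6", Operation.GT, 3.0), ("1751-7", Operation.LT, 30.0)), "and"),
    "N10": ((("6690-2", Operation.GT, 11.0), ("1988-5", Operation.GT, 50.0)), "and"),
    "K75": ((("1742-6", Operation.GT, 90.0), ("1920-8", Operation.GT, 80.0)), "and"),
    "K71": ((("1742-6", Operation.GT, 135.0), ("1975-2", Operation.GT, 40.0)), "and"),
    "K81": ((("6690-2", Operation.GT, 10.0), ("1975-2", Operation.GT, 21.0)), "and"),
    "K85": ((("3040-3", Operation.GT, 180.0), ("1798-8", Operation.GT, 300.0)), "or"),
    "E05": ((("3016-3", Operation.LT, 0.1), ("3024-7", Operation.GT, 22.0)), "and"),
    "D50": ((("718-7", Operation.LT, 120.0), ("2276-4", Operation.LT, 30.0)), "and"),
    "D72": ((("6690-2", Operation.GT, 25.0), ("751-8", Operation.LT, 1.5)), "or"),
    "N41": ((("2857-1", Operation.GT, 4.0), ("5821-4", Operation.GT, 10.0)), "and"),
}


def demo_rule_kb() -> RuleKnowledgeBase:
    """The packaged demo knowledge base.

    One interpretation rule set per ICD-10 group in :data:`ICD10_GROUPS`
    (two operation rules on LOINC-coded analytes combined into one
    aggregate rule concluding a Diagnosis artifact coded to the group),
    plus a type-2-diabetes risk-assessment rule set over glucose, BMI and
    age concluding Risk artifacts.
    """
    definitions: dict[str, Definition] = {}
    op_rules: list[OperationRule] = []
    ag_rules: list[AggregateRule] = []
    artifacts: list[Artifact] = []

    def def_for(loinc: str) -> Definition:
        did = f"def-{loinc}"
        if did not in definitions:
            display, _ = _ANALYTES[loinc]
            definitions[did] = Definition(did, CodedConcept(LOINC, loinc, display))
        return definitions[did]

    def op_rule(rule_id: str, loinc: str, op: Operation, value) -> OperationRule:
        display, unit = _ANALYTES[loinc]
        rule = OperationRule(
            id=rule_id,
            definition_id=def_for(loinc).id,
            operation=op,
            value=value,
            unit=unit,
            nomenclature=display,
            code=loinc,
            name=f"{display} {op.value} {value}",
        )
        op_rules.append(rule)
        return rule

    for group, (conds, combiner) in _GROUP_RULES.items():
        leaves = []
        for j, (loinc, op, value) in enumerate(conds, start=1):
            leaves.append(Leaf(op_rule(f"op-{group.lower()}-{j}", loinc, op, value).id))
        tree = And(tuple(leaves)) if combiner == "and" else Or(tuple(leaves))
        name = ICD10_GROUPS[group]
        artifacts.append(
            Artifact(
                id=f"art-{group.lower()}",
                type=ArtifactType.DIAGNOSIS,
                text=f"Laboratory pattern consistent with {name} ({group}). {PROVENANCE}.",
                concept=CodedConcept(ICD10, group, name),
            )
        )
        ag_rules.append(AggregateRule(f"ag-{group.lower()}", tree, f"art-{group.lower()}"))

    # Type-2-diabetes risk rule set: elevated fasting glucose combined with
    # obesity or age concludes high risk; impaired fasting glucose with
    # obesity concludes moderate risk.
    glu_high = op_rule("op-t2d-glucose-high", "2345-7", Operation.GT, 6.9)
    glu_impaired = op_rule("op-t2d-glucose-impaired", "2345-7", Operation.IN_RANGE, (5.6, 6.9))
    bmi_obese = op_rule("op-t2d-bmi", "39156-5", Operation.GE, 30.0)
    age_45 = op_rule("op-t2d-age", "30525-0", Operation.GE, 45.0)

    artifacts.append(
        Artifact(
            id="art-t2d-high",
            type=ArtifactType.RISK,
            text=f"High risk of type 2 diabetes; confirmatory testing advised. {PROVENANCE}.",
            concept=CodedConcept(ICD10, "E11", "Type 2 diabetes mellitus"),
        )
    )
    artifacts.append(
        Artifact(
            id="art-t2d-moderate",
            type=ArtifactType.RISK,
            text=f"Moderate risk of type 2 diabetes; lifestyle counselling advised. {PROVENANCE}.",
            concept=CodedConcept(ICD10, "R73.0", "Impaired fasting glucose"),
        )
    )
    ag_rules.append(
        AggregateRule(
            "ag-t2d-high",
            Or((And((Leaf(glu_high.id), Leaf(bmi_obese.id))),
                And((Leaf(glu_high.id), Leaf(age_45.id))))),
            "art-t2d-high",
        )
    )
    ag_rules.append(
        AggregateRule(
            "ag-t2d-moderate",
            And((Leaf(glu_impaired.id), Leaf(bmi_obese.id))),
            "art-t2d-moderate",
        )
    )

    return RuleKnowledgeBase.build(
        id="demo-interpretation-kb",
        definitions=definitions.values(),
        operation_rules=op_rules,
        aggregate_rules=ag_rules,
        artifacts=artifacts,
        metadata={
            "provenance": PROVENANCE,
            "illustrative": True,
            "icd10_groups": sorted(ICD10_GROUPS),
        },
    )


def demo_respiratory_model() -> BayesianModel:
    """Demo diagnostic network for respiratory complaints.

    Two diagnosis nodes (pneumonia, acute respiratory disease) and three
    SNOMED-coded findings — chill, right-sided chest pain on cough, rusty
    sputum — whose constructed CPTs each support pneumonia, so adding any
    of the findings raises its posterior. Carries two fixture signoffs,
    hence accepted status.
    """
    b = ("absent", "present")
    nodes = [
        BayesNode(
            id="pneumonia",
            concept=CodedConcept(SNOMED_CT, "233604007", "Pneumonia"),
            role=NodeRole.DIAGNOSIS,
            states=b,
            cpt=(CptRow.make({}, {"absent": 0.95, "present": 0.05}),),
        ),
        BayesNode(
            id="ard",
            concept=CodedConcept(SNOMED_CT, "54150009", "Acute respiratory disease"),
            role=NodeRole.DIAGNOSIS,
            states=b,
            cpt=(CptRow.make({}, {"absent": 0.70, "present": 0.30}),),
        ),
        BayesNode(
            id="chill",
            concept=CodedConcept(SNOMED_CT, "43724002", "Chill"),
            role=NodeRole.SYMPTOM,
            states=b,
            parents=("pneumonia", "ard"),
            cpt=(
                CptRow.make({"pneumonia": "absent", "ard": "absent"},
                            {"absent": 0.95, "present": 0.05}),
                CptRow.make({"pneumonia": "absent", "ard": "present"},
                            {"absent": 0.40, "present": 0.60}),
                CptRow.make({"pneumonia": "present", "ard": "absent"},
                            {"absent": 0.15, "present": 0.85}),
                CptRow.make({"pneumonia": "present", "ard": "present"},
                            {"absent": 0.05, "present": 0.95}),
            ),
        ),
        BayesNode(
            id="chest_pain_right",
            concept=CodedConcept(SNOMED_CT, "29857009", "Right-sided chest pain on cough"),
            role=NodeRole.SYMPTOM,
            states=b,
            parents=("pneumonia",),
            cpt=(
                CptRow.make({"pneumonia": "absent"}, {"absent": 0.95, "present": 0.05}),
                CptRow.make({"pneumonia": "present"}, {"absent": 0.30, "present": 0.70}),
            ),
        ),
        BayesNode(
            id="rusty_sputum",
            concept=CodedConcept(SNOMED_CT, "248595008", "Rusty sputum"),
            role=NodeRole.SYMPTOM,
            states=b,
            parents=("pneumonia",),
            cpt=(
                CptRow.make({"pneumonia": "absent"}, {"absent": 0.99, "present": 0.01}),
                CptRow.make({"pneumonia": "present"}, {"absent": 0.60, "present": 0.40}),
            ),
        ),
        BayesNode(
            id="fever",
            concept=CodedConcept(LOINC, "8310-5", "Body temperature"),
            role=NodeRole.OBJECTIVE_SIGN,
            states=("normal", "fever"),
            parents=("pneumonia", "ard"),
            cpt=(
                CptRow.make({"pneumonia": "absent", "ard": "absent"},
                            {"normal": 0.97, "fever": 0.03}),
                CptRow.make({"pneumonia": "absent", "ard": "present"},
                            {"normal": 0.50, "fever": 0.50}),
                CptRow.make({"pneumonia": "present", "ard": "absent"},
                            {"normal": 0.20, "fever": 0.80}),
                CptRow.make({"pneumonia": "present", "ard": "present"},
                            {"normal": 0.10, "fever": 0.90}),
            ),
            strata=(
                Stratum("normal", None, 38.0),
                Stratum("fever", 38.0, None),
            ),
            positive_state="fever",
        ),
    ]
    return BayesianModel(
        id="demo-respiratory",
        nodes=nodes,
        validation=ModelValidation(
            status=ValidationStatus.ACCEPTED,
            signoffs=["fixture-expert-1", "fixture-expert-2"],
        ),
        metadata={"provenance": PROVENANCE, "illustrative": True},
    )
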