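"""Canonical medication and side-effect vocabularies.

All tabular layouts in the package key off these lists; order is fixed and
meaningful (column order in phenotype files, manifest order in the factor
models).
"""

from __future__ import annotations

DRUGS: tuple[str, ...] = (
    "sertraline",
    "escitalopram",
    "venlafaxine",
    "fluoxetine",
    "citalopram",
    "desvenlafaxine",
    "duloxetine",
    "mirtazapine",
    "amitriptyline",
    "paroxetine",
)

SSRI_DRUGS: frozenset[str] = frozenset(
    {"sertraline", "escitalopram", "fluoxetine", "citalopram", "paroxetine"}
)
SNRI_DRUGS: frozenset[str] = frozenset(
    {"venlafaxine", "desvenlafaxine", "duloxetine"}
)
OTHER_DRUGS: frozenset[str] = frozenset({"mirtazapine", "amitriptyline"})

#: drug -> {"SSRI", "SNRI", "other"}
DRUG_CLASS: dict[str, str] = {
    **{d: "SSRI" for d in SSRI_DRUGS},
    **{d: "SNRI" for d in SNRI_DRUGS},
    **{d: "other" for d in OTHER_DRUGS},
}

#: The 23-item side-effect checklist.
CHECKLIST_EFFECTS: tuple[str, ...] = (
    "reduced_sexual_desire",
    "weight_gain",
    "dry_mouth",
    "nausea",
    "drowsiness",
    "insomnia",
    "dizziness",
    "fatigue",
    "sweating",
    "headache",
    "suicidal_thoughts",
    "anxiety",
    "agitation",
    "shaking",
    "constipation",
    "diarrhoea",
    "suicide_attempt",
    "blurred_vision",
    "muscle_pain",
    "vomiting",
    "weight_loss",
    "runny_nose",
    "rash",
)

OTHER_EFFECT = "other_side_effects"
NO_EFFECT = "no_side_effects"

#: The 25 phenotype columns per medication: checklist + catch-all + none.
ALL_EFFECTS: tuple[str, ...] = CHECKLIST_EFFECTS + (OTHER_EFFECT, NO_EFFECT)


def exposure_col(drug: str) -> str:
    return f"taken_{drug}"


def endorsement_col(drug: str, effect: str) -> str:
    return f"se_{drug}_{effect}"
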