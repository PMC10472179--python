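"""Canonical food-parameter vocabulary for the dietary inflammatory index.

The DII is defined over 45 food parameters (nutrients, foods and spices) each
carrying a literature-derived inflammatory effect weight. Identifiers here are
snake_case; ``PARAMETERS_45`` is the full vocabulary and ``PARAMETERS_28`` the
subset typically measurable from a 3-day meal-review survey joined against a
national food-composition table (energy, macronutrients, common micronutrients
and a handful of flavouring foods).
"""

from __future__ import annotations

PARAMETERS_45: tuple[str, ...] = (
    "alcohol",
    "vitamin_b12",
    "vitamin_b6",
    "beta_carotene",
    "caffeine",
    "carbohydrate",
    "cholesterol",
    "energy",
    "eugenol",
    "total_fat",
    "fiber",
    "folic_acid",
    "garlic",
    "ginger",
    "iron",
    "magnesium",
    "mufa",
    "niacin",
    "n3_fatty_acids",
    "n6_fatty_acids",
    "onion",
    "protein",
    "pufa",
    "riboflavin",
    "saffron",
    "saturated_fat",
    "selenium",
    "thiamine",
    "trans_fat",
    "turmeric",
    "vitamin_a",
    "vitamin_c",
    "vitamin_d",
    "vitamin_e",
    "zinc",
    "tea",
    "flavan_3_ols",
    "flavones",
    "flavonols",
    "flavanones",
    "anthocyanidins",
    "isoflavones",
    "pepper",
    "rosemary",
    "thyme_oregano",
)

# Survey-measurable subset: energy + macros, common micronutrients, fatty-acid
# classes, isoflavones, and flavouring foods (garlic, ginger, onion, tea,
# pepper, thyme/oregano).
PARAMETERS_28: tuple[str, ...] = (
    "energy",
    "carbohydrate",
    "protein",
    "total_fat",
    "alcohol",
    "beta_carotene",
    "cholesterol",
    "fiber",
    "folic_acid",
    "niacin",
    "iron",
    "magnesium",
    "selenium",
    "zinc",
    "mufa",
    "pufa",
    "isoflavones",
    "thiamine",
    "riboflavin",
    "saturated_fat",
    "vitamin_a",
    "vitamin_c",
    "garlic",
    "ginger",
    "onion",
    "tea",
    "pepper",
    "thyme_oregano",
)

# Per-component survival analyses are supported for these nutrients.
COMPONENT_ANALYSIS_NUTRIENTS: tuple[str, ...] = (
    "carbohydrate",
    "total_fat",
    "protein",
    "thiamine",
    "riboflavin",
    "niacin",
    "folic_acid",
    "vitamin_a",
    "iron",
    "selenium",
    "zinc",
    "magnesium",
)

assert len(PARAMETERS_45) == 45
assert len(PARAMETERS_28) == 28
assert set(PARAMETERS_28) <= set(PARAMETERS_45)
assert set(COMPONENT_ANALYSIS_NUTRIENTS) <= set(PARAMETERS_28)
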