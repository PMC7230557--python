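"""Default reference tables.

Everything here is configuration, not measurement: the food-composition
matrix, the inflammatory-index parameter table and the Mediterranean-diet
screener criteria shipped below are plausible defaults for an older
Spanish/Mediterranean cohort, intended so the pipeline runs end-to-end and
is testable.  Every table can be replaced through the run configuration;
analyses of real data should substitute the composition database and
reference tables used in the field.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# FFQ frequency vocabulary
# --------------------------------------------------------------------------

#: The nine ordered consumption-frequency categories of the semi-quantitative
#: 143-item FFQ, lowest to highest.
FREQUENCY_CATEGORIES: tuple[str, ...] = (
    "never or almost never",
    "1-3 times/month",
    "1 time/week",
    "2-4 times/week",
    "5-6 times/week",
    "1 time/day",
    "2-3 times/day",
    "4-6 times/day",
    ">=6 times/day",
)

#: Category midpoints expressed as servings per day.  Weekly categories use
#: the interval midpoint divided by 7 (e.g. 5-6/week -> 5.5/7); monthly uses
#: 2 per 30.4-day month.  Full precision is kept here; the two-decimal
#: truncating display convention lives in :func:`metsev.dietary.paper_format`.
FREQUENCY_PER_DAY: dict[str, float] = {
    "never or almost never": 0.0,
    "1-3 times/month": 2.0 / 30.4,
    "1 time/week": 1.0 / 7.0,
    "2-4 times/week": 3.0 / 7.0,
    "5-6 times/week": 5.5 / 7.0,
    "1 time/day": 1.0,
    "2-3 times/day": 2.5,
    "4-6 times/day": 5.0,
    ">=6 times/day": 6.0,
}

# --------------------------------------------------------------------------
# Sedentary-behaviour category mapping (12 categories, 0 .. >=9 h/day)
# --------------------------------------------------------------------------

#: Hours/day assigned to sitting-time categories 1..12.  The instrument's
#: printed anchors are 0 (bottom) and ">=9 h/day" (top, mapped to its lower
#: bound); intermediate categories are a declared convention, configurable.
SEDENTARY_CATEGORY_HOURS: tuple[float, ...] = (
    0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0,
)

# --------------------------------------------------------------------------
# Harmonized metabolic-syndrome thresholds
# --------------------------------------------------------------------------

#: Joint-society harmonized MetS component thresholds.  Sex-specific entries
#: are (men, women).  Risk direction is "high" except HDL, which is "low".
MET_S_THRESHOLDS: dict[str, object] = {
    "wc": (102.0, 88.0),       # cm
    "tag": 150.0,              # mg/dL
    "hdl": (40.0, 50.0),       # mg/dL, risk when below
    "sbp": 130.0,              # mmHg
    "dbp": 85.0,               # mmHg
    "glucose": 100.0,          # mg/dL
}

#: Default per-component scales for the severity score: approximate
#: population SDs in the same units as the thresholds.
MET_S_SCALES: dict[str, float] = {
    "wc": 9.0,
    "tag": 60.0,
    "hdl": 11.0,
    "sbp": 16.0,
    "dbp": 9.5,
    "glucose": 28.0,
}

# --------------------------------------------------------------------------
# Food groups and the 143-item composition table
# --------------------------------------------------------------------------

#: item counts per food group; the counts sum to exactly 143.
FOOD_GROUP_ITEM_COUNTS: dict[str, int] = {
    "fruits": 16,
    "vegetables": 18,
    "sofrito": 2,
    "potatoes": 3,
    "legumes": 5,
    "refined_cereals": 10,
    "whole_cereals": 4,
    "fish_seafood": 12,
    "red_meat": 6,
    "processed_meat": 6,
    "white_meat": 4,
    "eggs": 2,
    "dairy": 10,
    "butter_cream": 2,
    "nuts": 4,
    "olive_oil": 3,
    "other_oils": 3,
    "sweets_pastries": 10,
    "sugary_drinks": 3,
    "snacks": 5,
    "wine_beer": 4,
    "spirits": 3,
    "tea": 2,
    "coffee": 3,
    "garlic": 1,
    "onion": 2,
}

#: nutrient columns of the composition table / nutrient profile, with units.
NUTRIENT_COLUMNS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "carbohydrate_g",
    "fat_g",
    "sfa_g",
    "mufa_g",
    "pufa_g",
    "tfa_g",
    "omega3_g",
    "omega6_g",
    "linoleic_g",
    "cholesterol_mg",
    "fibre_g",
    "alcohol_g",
    "vitamin_a_ug",
    "vitamin_b1_mg",
    "vitamin_b2_mg",
    "vitamin_b3_mg",
    "vitamin_b6_mg",
    "vitamin_b9_ug",
    "vitamin_b12_ug",
    "vitamin_c_mg",
    "vitamin_d_ug",
    "vitamin_e_mg",
    "calcium_mg",
    "phosphorus_mg",
    "magnesium_mg",
    "iron_mg",
    "iodine_ug",
    "potassium_mg",
    "selenium_ug",
    "zinc_mg",
    "sodium_mg",
)

# per-100 g nutrient templates by food group, plus typical portion (g) and
# glycaemic index.  Values are rounded literature-typical figures.
_G = {
    # group: (portion_g, gi, {nutrient per 100 g})
    "fruits": (150, 45, dict(energy_kcal=55, protein_g=0.7, carbohydrate_g=13, fat_g=0.2,
                             fibre_g=2.2, vitamin_c_mg=30, vitamin_a_ug=30, vitamin_b9_ug=20,
                             potassium_mg=200, magnesium_mg=12, vitamin_b6_mg=0.08,
                             vitamin_e_mg=0.4, iodine_ug=2, sodium_mg=2, calcium_mg=12,
                             phosphorus_mg=18, iron_mg=0.3, zinc_mg=0.1, selenium_ug=0.5,
                             vitamin_b1_mg=0.03, vitamin_b2_mg=0.03, vitamin_b3_mg=0.4)),
    "vegetables": (150, 35, dict(energy_kcal=30, protein_g=1.5, carbohydrate_g=4.5, fat_g=0.3,
                                 fibre_g=2.5, vitamin_c_mg=35, vitamin_a_ug=200, vitamin_b9_ug=60,
                                 potassium_mg=280, magnesium_mg=18, vitamin_b6_mg=0.12,
                                 vitamin_e_mg=0.9, iodine_ug=3, sodium_mg=20, calcium_mg=40,
                                 phosphorus_mg=40, iron_mg=0.8, zinc_mg=0.3, selenium_ug=0.8,
                                 vitamin_b1_mg=0.06, vitamin_b2_mg=0.06, vitamin_b3_mg=0.7)),
    "sofrito": (60, 30, dict(energy_kcal=90, protein_g=1.5, carbohydrate_g=6, fat_g=6.5,
                             mufa_g=4.5, pufa_g=0.8, sfa_g=1.0, fibre_g=2.0, vitamin_c_mg=20,
                             vitamin_a_ug=80, vitamin_e_mg=1.5, potassium_mg=300,
                             magnesium_mg=15, sodium_mg=200, vitamin_b9_ug=25,
                             vitamin_b6_mg=0.15, iron_mg=0.6, zinc_mg=0.3)),
    "potatoes": (150, 75, dict(energy_kcal=80, protein_g=2, carbohydrate_g=18, fat_g=0.1,
                               fibre_g=1.8, vitamin_c_mg=12, potassium_mg=420, magnesium_mg=22,
                               vitamin_b6_mg=0.3, iron_mg=0.8, zinc_mg=0.3, vitamin_b3_mg=1.1,
                               vitamin_b1_mg=0.08, phosphorus_mg=55, sodium_mg=6)),
    "legumes": (150, 30, dict(energy_kcal=115, protein_g=8, carbohydrate_g=17, fat_g=0.6,
                              fibre_g=7, vitamin_b9_ug=120, iron_mg=2.5, magnesium_mg=45,
                              zinc_mg=1.2, potassium_mg=350, phosphorus_mg=130, calcium_mg=45,
                              selenium_ug=3, vitamin_b1_mg=0.2, vitamin_b3_mg=0.9,
                              vitamin_b6_mg=0.15, sodium_mg=5)),
    "refined_cereals": (60, 72, dict(energy_kcal=270, protein_g=8.5, carbohydrate_g=55, fat_g=1.5,
                                     sfa_g=0.3, fibre_g=3, iron_mg=1.5, magnesium_mg=25,
                                     zinc_mg=0.9, vitamin_b1_mg=0.12, vitamin_b2_mg=0.06,
                                     vitamin_b3_mg=1.8, vitamin_b9_ug=25, selenium_ug=8,
                                     phosphorus_mg=110, potassium_mg=130, sodium_mg=400,
                                     calcium_mg=25)),
    "whole_cereals": (60, 55, dict(energy_kcal=250, protein_g=9.5, carbohydrate_g=47, fat_g=2.5,
                                   pufa_g=1.0, fibre_g=8.5, iron_mg=2.8, magnesium_mg=90,
                                   zinc_mg=2.0, vitamin_b1_mg=0.3, vitamin_b2_mg=0.1,
                                   vitamin_b3_mg=4.5, vitamin_b6_mg=0.25, vitamin_b9_ug=40,
                                   selenium_ug=25, phosphorus_mg=250, potassium_mg=250,
                                   sodium_mg=350, vitamin_e_mg=1.0, calcium_mg=30)),
    "fish_seafood": (125, 0, dict(energy_kcal=130, protein_g=19, fat_g=5.5, sfa_g=1.2,
                                  mufa_g=1.8, pufa_g=1.8, omega3_g=1.3, cholesterol_mg=60,
                                  vitamin_d_ug=5.0, vitamin_b12_ug=4.5, selenium_ug=35,
                                  iodine_ug=40, zinc_mg=0.8, iron_mg=0.9, potassium_mg=330,
                                  phosphorus_mg=220, magnesium_mg=28, sodium_mg=100,
                                  vitamin_b3_mg=5.5, vitamin_b6_mg=0.4, vitamin_e_mg=0.8,
                                  calcium_mg=25)),
    "red_meat": (125, 0, dict(energy_kcal=210, protein_g=20, fat_g=14, sfa_g=5.5, mufa_g=6.0,
                              pufa_g=0.9, tfa_g=0.25, cholesterol_mg=75, iron_mg=2.2,
                              zinc_mg=4.2, vitamin_b12_ug=2.2, vitamin_b3_mg=5.0,
                              vitamin_b6_mg=0.35, selenium_ug=10, phosphorus_mg=180,
                              potassium_mg=320, magnesium_mg=20, sodium_mg=70,
                              vitamin_b1_mg=0.08, vitamin_b2_mg=0.2, vitamin_d_ug=0.3)),
    "processed_meat": (50, 0, dict(energy_kcal=310, protein_g=15, fat_g=27, sfa_g=9.5,
                                   mufa_g=12, pufa_g=2.7, tfa_g=0.5, cholesterol_mg=70,
                                   sodium_mg=1100, iron_mg=1.4, zinc_mg=2.1,
                                   vitamin_b12_ug=1.3, vitamin_b1_mg=0.3, iodine_ug=12,
                                   selenium_ug=12, phosphorus_mg=180, potassium_mg=230,
                                   magnesium_mg=16, vitamin_b3_mg=3.5, vitamin_b6_mg=0.2)),
    "white_meat": (125, 0, dict(energy_kcal=150, protein_g=21, fat_g=7, sfa_g=2.0, mufa_g=3.0,
                                pufa_g=1.4, cholesterol_mg=70, iron_mg=0.9, zinc_mg=1.3,
                                vitamin_b12_ug=0.5, vitamin_b3_mg=8.5, vitamin_b6_mg=0.5,
                                selenium_ug=14, phosphorus_mg=200, potassium_mg=300,
                                magnesium_mg=25, sodium_mg=75, vitamin_b2_mg=0.15)),
    "eggs": (60, 0, dict(energy_kcal=145, protein_g=12.5, fat_g=10, sfa_g=3.1, mufa_g=4.0,
                         pufa_g=1.4, cholesterol_mg=370, vitamin_a_ug=160, vitamin_d_ug=1.8,
                         vitamin_b12_ug=1.1, vitamin_b2_mg=0.45, vitamin_b9_ug=50,
                         selenium_ug=30, iodine_ug=50, iron_mg=1.9, zinc_mg=1.3,
                         phosphorus_mg=200, sodium_mg=140, calcium_mg=55, vitamin_e_mg=1.1)),
    "dairy": (200, 30, dict(energy_kcal=60, protein_g=3.3, carbohydrate_g=4.8, fat_g=2.4,
                            sfa_g=1.5, mufa_g=0.7, tfa_g=0.08, cholesterol_mg=9,
                            calcium_mg=120, phosphorus_mg=95, iodine_ug=22, vitamin_b2_mg=0.18,
                            vitamin_b12_ug=0.4, vitamin_d_ug=0.3, vitamin_a_ug=35,
                            potassium_mg=150, magnesium_mg=11, zinc_mg=0.4, sodium_mg=45,
                            selenium_ug=1.5, vitamin_b1_mg=0.04)),
    "butter_cream": (12, 0, dict(energy_kcal=730, protein_g=0.7, fat_g=81, sfa_g=51, mufa_g=21,
                                 pufa_g=2.5, tfa_g=3.0, cholesterol_mg=215, vitamin_a_ug=670,
                                 vitamin_d_ug=1.3, vitamin_e_mg=2.2, sodium_mg=12,
                                 calcium_mg=18)),
    "nuts": (30, 15, dict(energy_kcal=610, protein_g=17, carbohydrate_g=7, fat_g=54, sfa_g=5.5,
                          mufa_g=28, pufa_g=17, omega3_g=2.0, omega6_g=14, linoleic_g=14,
                          fibre_g=8, vitamin_e_mg=12, magnesium_mg=200, zinc_mg=3.0,
                          iron_mg=3.0, selenium_ug=5, vitamin_b9_ug=60, potassium_mg=600,
                          phosphorus_mg=400, calcium_mg=90, vitamin_b1_mg=0.3,
                          vitamin_b3_mg=3.0, vitamin_b6_mg=0.4, sodium_mg=4)),
    "olive_oil": (10, 0, dict(energy_kcal=884, fat_g=100, sfa_g=14, mufa_g=73, pufa_g=9,
                              linoleic_g=8, omega6_g=8, omega3_g=0.7, vitamin_e_mg=14)),
    "other_oils": (10, 0, dict(energy_kcal=884, fat_g=100, sfa_g=12, mufa_g=28, pufa_g=55,
                               linoleic_g=50, omega6_g=52, omega3_g=1.0, tfa_g=0.8,
                               vitamin_e_mg=25)),
    "sweets_pastries": (50, 65, dict(energy_kcal=430, protein_g=5.5, carbohydrate_g=58,
                                     fat_g=19, sfa_g=8.5, mufa_g=7, pufa_g=2.5, tfa_g=1.0,
                                     cholesterol_mg=55, fibre_g=1.8, sodium_mg=300,
                                     calcium_mg=60, iron_mg=1.5, vitamin_e_mg=1.5,
                                     vitamin_b2_mg=0.1, phosphorus_mg=120, potassium_mg=130,
                                     magnesium_mg=18, zinc_mg=0.6)),
    "sugary_drinks": (200, 63, dict(energy_kcal=42, carbohydrate_g=10.5, sodium_mg=8,
                                    potassium_mg=5)),
    "snacks": (50, 55, dict(energy_kcal=480, protein_g=6.5, carbohydrate_g=50, fat_g=28,
                            sfa_g=6, mufa_g=12, pufa_g=8, tfa_g=0.7, linoleic_g=7, omega6_g=7,
                            fibre_g=3.5, sodium_mg=900, potassium_mg=800, magnesium_mg=50,
                            iron_mg=1.6, zinc_mg=1.5, vitamin_e_mg=4, vitamin_b6_mg=0.3)),
    "wine_beer": (150, 0, dict(energy_kcal=65, carbohydrate_g=2.5, alcohol_g=7.5,
                               potassium_mg=80, magnesium_mg=9, iron_mg=0.4)),
    "spirits": (40, 0, dict(energy_kcal=230, alcohol_g=33)),
    "tea": (200, 0, dict(energy_kcal=1, potassium_mg=18, magnesium_mg=2)),
    "coffee": (50, 0, dict(energy_kcal=2, potassium_mg=50, magnesium_mg=4, vitamin_b3_mg=0.6)),
    "garlic": (5, 0, dict(energy_kcal=120, protein_g=5.5, carbohydrate_g=24, fibre_g=1.8,
                          vitamin_c_mg=14, vitamin_b6_mg=0.8, selenium_ug=14, calcium_mg=140,
                          potassium_mg=400, magnesium_mg=25, iron_mg=1.5, zinc_mg=1.1,
                          sodium_mg=14)),
    "onion": (50, 25, dict(energy_kcal=33, protein_g=1.2, carbohydrate_g=6.5, fibre_g=1.5,
                           vitamin_c_mg=7, vitamin_b9_ug=18, potassium_mg=160,
                           magnesium_mg=10, calcium_mg=25, sodium_mg=3)),
}


def default_food_composition() -> pd.DataFrame:
    """Build the default 143-item food-composition table.

    Each FFQ item carries its food group, a typical portion size (g), a
    glycaemic index and a full per-portion nutrient vector.  Within a group,
    items vary deterministically around the group template (+/-20%) so that
    item-level heterogeneity exists without any randomness.

    Returns a DataFrame indexed by ``item_id`` (``item_001`` ... ``item_143``).
    """
    rows = []
    idx = 0
    for group, count in FOOD_GROUP_ITEM_COUNTS.items():
        portion, gi, per100 = _G[group]
        for j in range(count):
            idx += 1
            # deterministic +/-20% spread across the group's items
            jitter = 0.8 + 0.4 * ((idx * 37) % 101) / 100.0
            row = {"item_id": f"item_{idx:03d}", "food_group": group,
                   "portion_g": float(portion), "gi": float(gi)}
            for col in NUTRIENT_COLUMNS:
                per100_val = per100.get(col, 0.0)
                row[col] = per100_val * (portion / 100.0) * jitter
            rows.append(row)
    fct = pd.DataFrame(rows).set_index("item_id")
    assert len(fct) == 143
    return fct


# --------------------------------------------------------------------------
# Dietary Inflammatory Index parameter table (30 food parameters)
# --------------------------------------------------------------------------

# name -> (profile variable, reference mean, reference SD, inflammatory effect
# score; positive = pro-inflammatory).  Means/SDs are package defaults for an
# older Mediterranean population; effect-score signs follow the conventional
# pro/anti-inflammatory classification of each parameter.
_DII_ROWS = [
    ("energy", "energy_kcal", 2350.0, 550.0, 0.180),
    ("carbohydrate", "carbohydrate_g", 240.0, 60.0, 0.097),
    ("protein", "protein_g", 98.0, 22.0, 0.021),
    ("total_fat", "fat_g", 103.0, 27.0, 0.298),
    ("sfa", "sfa_g", 26.0, 7.0, 0.373),
    ("mufa", "mufa_g", 53.0, 15.0, -0.009),
    ("pufa", "pufa_g", 16.5, 6.0, -0.337),
    ("tfa", "tfa_g", 0.6, 0.4, 0.229),
    ("omega3", "omega3_g", 2.3, 0.9, -0.436),
    ("omega6", "omega6_g", 13.0, 5.5, -0.159),
    ("cholesterol", "cholesterol_mg", 380.0, 118.0, 0.110),
    ("fibre", "fibre_g", 26.0, 9.0, -0.663),
    ("alcohol", "alcohol_g", 11.0, 15.0, -0.278),
    ("vitamin_a", "vitamin_a_ug", 1100.0, 640.0, -0.401),
    ("thiamine", "vitamin_b1_mg", 1.6, 0.4, -0.098),
    ("riboflavin", "vitamin_b2_mg", 2.0, 0.6, -0.068),
    ("niacin", "vitamin_b3_mg", 40.0, 10.0, -0.246),
    ("vitamin_b6", "vitamin_b6_mg", 2.4, 0.6, -0.365),
    ("folic_acid", "vitamin_b9_ug", 350.0, 103.0, -0.190),
    ("vitamin_b12", "vitamin_b12_ug", 10.0, 4.5, 0.106),
    ("vitamin_c", "vitamin_c_mg", 200.0, 86.0, -0.424),
    ("vitamin_d", "vitamin_d_ug", 6.2, 3.5, -0.446),
    ("vitamin_e", "vitamin_e_mg", 10.6, 4.0, -0.419),
    ("magnesium", "magnesium_mg", 420.0, 110.0, -0.484),
    ("iron", "iron_mg", 16.5, 4.0, 0.032),
    ("zinc", "zinc_mg", 13.2, 3.3, -0.313),
    ("selenium", "selenium_ug", 117.0, 33.0, -0.191),
    ("garlic", "garlic_g", 3.0, 3.0, -0.412),
    ("tea", "tea_g", 60.0, 90.0, -0.536),
    ("onion", "onion_g", 30.0, 22.0, -0.301),
]


def default_dii_parameters() -> pd.DataFrame:
    """Default 30-parameter inflammatory-index table.

    Columns: ``variable`` (nutrient-profile or food-group column the
    parameter is read from), ``global_mean``, ``global_sd``, ``effect_score``.
    Indexed by parameter name.
    """
    t = pd.DataFrame(
        _DII_ROWS,
        columns=["parameter", "variable", "global_mean", "global_sd", "effect_score"],
    ).set_index("parameter")
    return t


# --------------------------------------------------------------------------
# 17-item Mediterranean-diet screener criteria
# --------------------------------------------------------------------------

# Each criterion is a predicate over the per-subject daily intake variables
# (food-group grams/day as "<group>_g", servings/day as "<group>_serv").
# "var2" entries compare two variables (preference items).
DEFAULT_MD17_CRITERIA: tuple[dict, ...] = (
    {"name": "olive_oil_main_fat", "var": "olive_oil_g", "op": "ge", "threshold": 20.0},
    {"name": "olive_oil_4tbsp", "var": "olive_oil_g", "op": "ge", "threshold": 40.0},
    {"name": "vegetables_2_per_day", "var": "vegetables_serv", "op": "ge", "threshold": 2.0},
    {"name": "fruit_3_per_day", "var": "fruits_serv", "op": "ge", "threshold": 3.0},
    {"name": "red_processed_meat_lt_1_per_day", "var": "red_processed_meat_serv",
     "op": "lt", "threshold": 1.0},
    {"name": "butter_cream_lt_1_per_day", "var": "butter_cream_serv", "op": "lt",
     "threshold": 1.0},
    {"name": "sugary_drinks_lt_1_per_day", "var": "sugary_drinks_serv", "op": "lt",
     "threshold": 1.0},
    {"name": "wine_1_per_day", "var": "wine_beer_serv", "op": "ge", "threshold": 1.0},
    {"name": "legumes_3_per_week", "var": "legumes_serv", "op": "ge", "threshold": 3.0 / 7.0},
    {"name": "fish_3_per_week", "var": "fish_seafood_serv", "op": "ge",
     "threshold": 3.0 / 7.0},
    {"name": "pastries_lt_2_per_week", "var": "sweets_pastries_serv", "op": "lt",
     "threshold": 2.0 / 7.0},
    {"name": "nuts_3_per_week", "var": "nuts_serv", "op": "ge", "threshold": 3.0 / 7.0},
    {"name": "white_meat_preference", "var": "white_meat_g", "op": "gt",
     "var2": "red_meat_g"},
    {"name": "sofrito_2_per_week", "var": "sofrito_serv", "op": "ge", "threshold": 2.0 / 7.0},
    {"name": "wholegrain_preference", "var": "whole_cereals_g", "op": "ge",
     "var2": "refined_cereals_g"},
    {"name": "snacks_lt_1_per_day", "var": "snacks_serv", "op": "lt", "threshold": 1.0},
    {"name": "spirits_lt_1_per_week", "var": "spirits_serv", "op": "lt",
     "threshold": 1.0 / 7.0},
)
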