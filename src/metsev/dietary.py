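"""FFQ processing, nutrient profiles, energy filters, MD-17 adherence and the
Dietary Inflammatory Index (DII).

The FFQ is a semi-quantitative 143-item instrument whose responses fall in
nine ordered frequency categories from "never or almost never" to ">=6
times/day".  Category midpoints are converted to servings/day, multiplied by
per-portion nutrient contents from a food-composition table and summed;
declared supplement intakes add to the micronutrient totals.

The DII assigns each of 30 food parameters a z-score against a global
reference mean/SD, maps it to a centred percentile c = 2*Phi(z) - 1 in
(-1, 1), and sums c times the parameter's literature-derived inflammatory
effect score.  Positive totals indicate a pro-inflammatory diet.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .reference import (
    DEFAULT_MD17_CRITERIA,
    FOOD_GROUP_ITEM_COUNTS,
    FREQUENCY_CATEGORIES,
    FREQUENCY_PER_DAY,
    NUTRIENT_COLUMNS,
    default_dii_parameters,
    default_food_composition,
)

__all__ = [
    "frequency_to_per_day",
    "paper_format",
    "compute_nutrient_profiles",
    "compute_food_groups",
    "energy_exclusion",
    "score_md17",
    "compute_dii",
]

# energy factors, kcal per gram
_KCAL_PER_G = {"carbohydrate_g": 4.0, "protein_g": 4.0, "fat_g": 9.0, "alcohol_g": 7.0}


def frequency_to_per_day(category: str) -> float:
    """Convert a frequency category to servings per day (full precision).

    >>> frequency_to_per_day("5-6 times/week")   # 5.5/7
    0.7857142857142857
    """
    try:
        return FREQUENCY_PER_DAY[category]
    except KeyError:
        raise ValueError(
            f"unknown frequency category {category!r}; "
            f"expected one of {list(FREQUENCY_CATEGORIES)}"
        ) from None


def paper_format(value: float, decimals: int = 2) -> str:
    """Format a value with the truncating (floor) display convention.

    Printed conventions in FFQ work truncate rather than round: 5.5/7 =
    0.7857... is displayed as ``0.78``.  Only for display; computations keep
    full precision.
    """
    factor = 10 ** decimals
    return f"{math.floor(value * factor) / factor:.{decimals}f}"


def _validate_responses(responses: pd.DataFrame) -> None:
    required = {"subject_id", "item_id", "category"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"FFQ responses missing columns: {sorted(missing)}")
    bad = set(responses["category"]) - set(FREQUENCY_CATEGORIES)
    if bad:
        raise ValueError(f"unknown frequency categories: {sorted(bad)}")


def compute_nutrient_profiles(
    responses: pd.DataFrame,
    fct: pd.DataFrame | None = None,
    supplements: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute per-subject daily nutrient profiles from FFQ responses.

    Parameters
    ----------
    responses
        Long-format FFQ responses with columns ``subject_id``, ``item_id``,
        ``category`` (one of the nine frequency levels).  An optional
        ``portion_g`` column overrides the composition table's portion size
        (nutrients are scaled proportionally).
    fct
        Food-composition table indexed by ``item_id`` with per-portion
        nutrient columns, ``portion_g`` and ``gi``.  Defaults to the built-in
        table.
    supplements
        Optional wide table indexed by ``subject_id`` with daily supplement
        contributions in nutrient-profile units; added to the food totals.

    Returns
    -------
    DataFrame indexed by ``subject_id`` with one column per nutrient, the
    intake-weighted glycaemic index ``gi`` and the macronutrient %-of-energy
    columns ``fat_pct_te``, ``carbohydrate_pct_te``, ``protein_pct_te``.
    """
    if fct is None:
        fct = default_food_composition()
    _validate_responses(responses)

    unmapped = set(responses["item_id"]) - set(fct.index)
    if unmapped:
        raise ValueError(f"FFQ items absent from composition table: {sorted(unmapped)}")
    if supplements is not None and (supplements.select_dtypes("number") < 0).any().any():
        raise ValueError("negative supplement intakes are not allowed")

    r = responses.copy()
    r["per_day"] = r["category"].map(FREQUENCY_PER_DAY)
    comp = fct.loc[r["item_id"], list(NUTRIENT_COLUMNS)].to_numpy()
    scale = r["per_day"].to_numpy()[:, None]
    if "portion_g" in r.columns:
        ref_portion = fct.loc[r["item_id"], "portion_g"].to_numpy()
        scale = scale * (r["portion_g"].to_numpy() / ref_portion)[:, None]
    contrib = pd.DataFrame(comp * scale, columns=list(NUTRIENT_COLUMNS))
    contrib["subject_id"] = r["subject_id"].to_numpy()
    profile = contrib.groupby("subject_id").sum()

    # carbohydrate-weighted glycaemic index
    carb = fct.loc[r["item_id"], "carbohydrate_g"].to_numpy() * scale[:, 0]
    gi_num = pd.Series(carb * fct.loc[r["item_id"], "gi"].to_numpy(),
                       index=r["subject_id"].to_numpy()).groupby(level=0).sum()
    gi_den = pd.Series(carb, index=r["subject_id"].to_numpy()).groupby(level=0).sum()
    profile["gi"] = (gi_num / gi_den.replace(0.0, np.nan)).fillna(0.0)

    if supplements is not None:
        supp = supplements.reindex(profile.index).fillna(0.0)
        for col in supp.columns:
            if col in profile.columns and col != "gi":
                profile[col] = profile[col] + supp[col]

    energy = profile["energy_kcal"].replace(0.0, np.nan)
    for macro, label in [("fat_g", "fat_pct_te"), ("carbohydrate_g", "carbohydrate_pct_te"),
                         ("protein_g", "protein_pct_te"), ("alcohol_g", "alcohol_pct_te")]:
        profile[label] = (100.0 * _KCAL_PER_G[macro] * profile[macro] / energy).fillna(0.0)
    return profile


def compute_food_groups(
    responses: pd.DataFrame, fct: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Aggregate FFQ responses into daily food-group intakes.

    Returns a DataFrame indexed by subject with ``<group>_g`` (grams/day) and
    ``<group>_serv`` (servings/day) per food group, plus the combined
    ``red_processed_meat`` and ``total_meat`` aggregates used in reporting.
    """
    if fct is None:
        fct = default_food_composition()
    _validate_responses(responses)
    r = responses.copy()
    r["per_day"] = r["category"].map(FREQUENCY_PER_DAY)
    r["group"] = fct.loc[r["item_id"], "food_group"].to_numpy()
    portion = fct.loc[r["item_id"], "portion_g"].to_numpy()
    if "portion_g" in responses.columns:
        portion = responses["portion_g"].to_numpy()
    r["grams"] = r["per_day"].to_numpy() * portion

    grams = r.pivot_table(index="subject_id", columns="group", values="grams",
                          aggfunc="sum", fill_value=0.0)
    servs = r.pivot_table(index="subject_id", columns="group", values="per_day",
                          aggfunc="sum", fill_value=0.0)
    out = pd.DataFrame(index=grams.index)
    for g in FOOD_GROUP_ITEM_COUNTS:
        out[f"{g}_g"] = grams.get(g, 0.0)
        out[f"{g}_serv"] = servs.get(g, 0.0)
    out["red_processed_meat_g"] = out["red_meat_g"] + out["processed_meat_g"]
    out["red_processed_meat_serv"] = out["red_meat_serv"] + out["processed_meat_serv"]
    out["total_meat_g"] = out["red_processed_meat_g"] + out["white_meat_g"]
    out["cereals_g"] = out["refined_cereals_g"] + out["whole_cereals_g"]
    return out


def energy_exclusion(energy_kcal, sex) -> pd.Series:
    """Flag subjects with extreme reported energy intake for exclusion.

    Women are excluded when intake is strictly below 500 or strictly above
    3500 kcal/day; men below 800 or above 4000.  Boundary values are kept.
    Missing energy is *not* flagged here (it is a missing-FFQ exclusion).

    Returns a boolean Series, True = exclude.
    """
    energy = pd.Series(np.asarray(energy_kcal, dtype=float))
    sex = pd.Series(np.asarray(sex, dtype=object)).str.lower()
    lo = sex.map({"female": 500.0, "male": 800.0})
    hi = sex.map({"female": 3500.0, "male": 4000.0})
    if lo.isna().any():
        raise ValueError("sex must be 'male' or 'female'")
    exclude = (energy < lo.to_numpy()) | (energy > hi.to_numpy())
    return exclude.fillna(False)


_OPS = {
    "ge": np.greater_equal,
    "gt": np.greater,
    "le": np.less_equal,
    "lt": np.less,
}


def score_md17(
    intakes: Mapping[str, float] | pd.DataFrame,
    criteria: Iterable[Mapping] = DEFAULT_MD17_CRITERIA,
) -> int | pd.Series:
    """Score adherence to the 17-item Mediterranean-diet screener.

    Each criterion is a 0/1 predicate over the daily food-group intake
    variables; the total is the number of criteria met, in [0, 17].
    Accepts a single subject's intake mapping or a cohort DataFrame
    (returns an integer Series).  A missing input variable makes the score
    missing for the affected subjects.
    """
    criteria = list(criteria)
    if len(criteria) != 17:
        raise ValueError(f"expected 17 criteria, got {len(criteria)}")

    single = not isinstance(intakes, pd.DataFrame)
    df = pd.DataFrame([intakes]) if single else intakes
    total = pd.Series(0.0, index=df.index)
    for crit in criteria:
        op = _OPS[crit["op"]]
        if crit["var"] not in df.columns:
            raise ValueError(f"MD-17 criterion {crit['name']!r}: missing variable "
                             f"{crit['var']!r}")
        lhs = df[crit["var"]].astype(float)
        if "var2" in crit:
            rhs = df[crit["var2"]].astype(float)
        else:
            rhs = crit["threshold"]
        met = op(lhs, rhs).astype(float)
        met[lhs.isna()] = np.nan
        total = total + met
    if single:
        v = total.iloc[0]
        return int(v) if not np.isnan(v) else float("nan")
    return total


def compute_dii(
    profile: Mapping[str, float] | pd.DataFrame,
    table: pd.DataFrame | None = None,
    method: str = "normal",
) -> float | pd.Series:
    """Compute the Dietary Inflammatory Index.

    For each food parameter j the intake is standardised against the
    reference table, z_j = (x_j - mean_j) / sd_j, converted to a centred
    percentile c_j in (-1, 1) and weighted by the parameter's inflammatory
    effect score:  DII = sum_j c_j * effect_j.

    ``method="normal"`` (default) takes the percentile as the standard-normal
    CDF of z_j, matching the global-reference-database construction;
    ``method="empirical"`` uses within-sample empirical percentiles instead
    (cohort input only).
    """
    if table is None:
        table = default_dii_parameters()
    if (table["global_sd"] <= 0).any():
        raise ValueError("global_sd must be positive for every DII parameter")

    single = not isinstance(profile, pd.DataFrame)
    df = pd.DataFrame([profile]) if single else profile
    missing = [v for v in table["variable"] if v not in df.columns]
    if missing:
        raise ValueError(f"profile lacks DII parameter variables: {missing}")

    x = df[list(table["variable"])].to_numpy(dtype=float)
    if method == "normal":
        z = (x - table["global_mean"].to_numpy()) / table["global_sd"].to_numpy()
        pct = norm.cdf(z)
    elif method == "empirical":
        if single:
            raise ValueError("empirical percentiles require a cohort DataFrame")
        pct = np.column_stack(
            [rankdata(x[:, j]) / (x.shape[0] + 1) for j in range(x.shape[1])]
        )
    else:
        raise ValueError(f"unknown DII method {method!r}")
    centred = 2.0 * pct - 1.0
    dii = centred @ table["effect_score"].to_numpy()
    if single:
        return float(dii[0])
    return pd.Series(dii, index=df.index, name="dii")
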