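"""Synthetic cohort generator.

Emulates the baseline data structure of an energy-restricted Mediterranean
lifestyle trial in older adults with overweight/obesity and metabolic
syndrome: men aged 55-75 and women 60-75 with BMI in [27, 40) and at least
three harmonized MetS criteria, correlated MetS components driven by one
latent severity factor, medication probabilities logistic in that factor,
and lifestyle variables (LTPA, sitting time, depression items, FFQ food
groups) optionally coupled to severity in the directions observed in such
cohorts (higher severity: less moderate/vigorous LTPA, more sitting time,
higher depression scores, more red/processed meat, fewer nuts).

The generator reproduces marginal locations/spreads and the *sign* of the
severity couplings, not the real cohort's full joint distribution.  All
randomness flows from one integer seed; identical spec -> byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .reference import (
    FOOD_GROUP_ITEM_COUNTS,
    FREQUENCY_CATEGORIES,
    SEDENTARY_CATEGORY_HOURS,
    default_food_composition,
)

__all__ = ["CohortSpec", "Cohort", "generate_cohort", "generate_ffq_responses"]

_COMPONENTS = ("wc", "sbp", "dbp", "glucose", "tag", "hdl")

# latent-severity tertile boundaries of a standard normal
_L_TERTILES = (norm.ppf(1.0 / 3.0), norm.ppf(2.0 / 3.0))


def _default_means():
    return {
        "male": {"wc": 111.0, "sbp": 139.0, "dbp": 82.0, "glucose": 114.0,
                 "tag": 150.0, "hdl": 44.0},
        "female": {"wc": 104.0, "sbp": 137.0, "dbp": 80.0, "glucose": 110.0,
                   "tag": 135.0, "hdl": 50.0},
    }


def _default_sds():
    # tag is a log-scale SD (triglycerides are generated log-normally,
    # component mean acting as the median)
    return {"wc": 8.0, "sbp": 16.0, "dbp": 9.5, "glucose": 26.0,
            "tag": 0.42, "hdl": 11.0}


def _default_loadings():
    return {"wc": 0.55, "sbp": 0.50, "dbp": 0.45, "glucose": 0.55,
            "tag": 0.50, "hdl": -0.45}


def _default_correlation():
    # residual correlation among components after the latent factor
    r = np.eye(6)
    ix = {c: i for i, c in enumerate(_COMPONENTS)}

    def set_(a, b, v):
        r[ix[a], ix[b]] = r[ix[b], ix[a]] = v

    set_("sbp", "dbp", 0.60)
    set_("tag", "hdl", -0.25)
    set_("wc", "glucose", 0.10)
    set_("wc", "sbp", 0.10)
    return r


def _default_effects():
    # shift (in SDs of the variable) between extreme latent-severity
    # tertiles, signed T3 minus T1
    return {
        "ltpa_light": 0.0, "ltpa_moderate": -0.20, "ltpa_vigorous": -0.20,
        "sedentary": 0.15, "tv": 0.10, "sleep": 0.0,
        "bdi": 0.25, "chair_stand": -0.30,
        "nuts": -0.15, "red_processed_meat": 0.15, "other_oils": 0.10,
        "spirits": 0.10, "education": -0.20, "smoking": 0.0,
        "marital": 0.0, "employment": 0.0,
    }


def _default_medication_logit():
    # drug class -> (intercept, slope on latent severity)
    return {
        "med_antihypertensive": (1.25, 0.30),
        "med_cholesterol": (0.10, 0.15),
        "med_insulin": (-3.20, 0.90),
        "med_oral_hypoglycaemic": (-1.30, 0.80),
        "med_aspirin": (-1.80, 0.35),
    }


@dataclass
class CohortSpec:
    """Generator configuration; defaults emulate the trial's baseline
    eligibility window and marginal distributions."""

    n_subjects: int = 1000
    fraction_women: float = 0.477
    age_range_men: tuple[float, float] = (55.0, 75.0)
    age_range_women: tuple[float, float] = (60.0, 75.0)
    bmi_range: tuple[float, float] = (27.0, 40.0)
    component_means_by_sex: dict = field(default_factory=_default_means)
    component_sds: dict = field(default_factory=_default_sds)
    component_loadings: dict = field(default_factory=_default_loadings)
    component_correlation: np.ndarray = field(default_factory=_default_correlation)
    effect_size_by_tertile: dict = field(default_factory=_default_effects)
    medication_logit: dict = field(default_factory=_default_medication_logit)
    missing_pa_rate: float = 0.034
    missing_ffq_rate: float = 0.006
    missing_cvd_rate: float = 0.081
    supplement_rate: float = 0.20
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        for name in ("fraction_women", "missing_pa_rate", "missing_ffq_rate",
                     "missing_cvd_rate", "supplement_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        r = np.asarray(self.component_correlation, dtype=float)
        if r.shape != (6, 6) or not np.allclose(r, r.T):
            raise ValueError("component_correlation must be a symmetric 6x6 matrix")
        try:
            np.linalg.cholesky(r)
        except np.linalg.LinAlgError:
            eig = np.linalg.eigvalsh(r).min()
            raise ValueError(
                "component_correlation is not positive-definite "
                f"(smallest eigenvalue {eig:.3g})") from None

    def null(self) -> "CohortSpec":
        """Copy of the spec with every severity coupling switched off
        (zero lifestyle effects, zero medication slopes, no missingness)."""
        return replace(
            self,
            effect_size_by_tertile={k: 0.0 for k in self.effect_size_by_tertile},
            medication_logit={k: (b0, 0.0) for k, (b0, _) in self.medication_logit.items()},
            missing_pa_rate=0.0, missing_ffq_rate=0.0, missing_cvd_rate=0.0,
        )


@dataclass
class Cohort:
    """Generated participant-level data: one wide subject table plus
    long-format companion tables keyed by ``subject_id``."""

    subjects: pd.DataFrame
    activity: pd.DataFrame
    bdi: pd.DataFrame
    supplements: pd.DataFrame
    spec: CohortSpec


def _effect(spec: CohortSpec, key: str) -> float:
    return float(spec.effect_size_by_tertile.get(key, 0.0))


def _tertile_shift(tert_idx: np.ndarray, effect_sd: float, sd: float) -> np.ndarray:
    """Mean shift per latent tertile: T3 - T1 equals effect_sd x sd."""
    return effect_sd * sd * (tert_idx - 1.0) / 2.0


def _draw_eligible(spec: CohortSpec, rng: np.random.Generator, n: int):
    """Draw one candidate batch and keep rows meeting eligibility."""
    female = rng.random(n) < spec.fraction_women
    sex = np.where(female, "female", "male").astype(object)
    lo = np.where(female, spec.age_range_women[0], spec.age_range_men[0])
    hi = np.where(female, spec.age_range_women[1], spec.age_range_men[1])
    age = rng.uniform(lo, hi)
    height = np.where(female, rng.normal(1.555, 0.055, n), rng.normal(1.67, 0.06, n))
    # BMI from a clipped normal, resampling the tails inside the window
    b_lo, b_hi = spec.bmi_range
    bmi = rng.normal(32.2, 3.0, n)
    bad = (bmi < b_lo) | (bmi >= b_hi)
    while bad.any():
        bmi[bad] = rng.normal(32.2, 3.0, bad.sum())
        bad = (bmi < b_lo) | (bmi >= b_hi)
    weight = bmi * height ** 2

    latent = rng.standard_normal(n)
    chol = np.linalg.cholesky(np.asarray(spec.component_correlation, dtype=float))
    resid = rng.standard_normal((n, 6)) @ chol.T

    comp = {}
    for j, c in enumerate(_COMPONENTS):
        lam = spec.component_loadings[c]
        mix = lam * latent + np.sqrt(max(0.0, 1.0 - lam ** 2)) * resid[:, j]
        mean = np.where(female, spec.component_means_by_sex["female"][c],
                        spec.component_means_by_sex["male"][c])
        sd = spec.component_sds[c]
        if c == "tag":
            comp[c] = mean * np.exp(sd * mix)   # log-normal, mean acts as median
        elif c == "wc":
            comp[c] = mean + 1.6 * (bmi - 32.2) + sd * mix
        else:
            comp[c] = mean + sd * mix
    comp["hdl"] = np.maximum(comp["hdl"], 20.0)
    comp["tag"] = np.maximum(comp["tag"], 40.0)
    comp["glucose"] = np.maximum(comp["glucose"], 60.0)

    # harmonized MetS criteria on raw values (>=3 of 5 to be eligible)
    wc_cut = np.where(female, 88.0, 102.0)
    hdl_cut = np.where(female, 50.0, 40.0)
    n_crit = (
        (comp["wc"] >= wc_cut).astype(int)
        + (comp["tag"] >= 150.0).astype(int)
        + (comp["hdl"] < hdl_cut).astype(int)
        + ((comp["sbp"] >= 130.0) | (comp["dbp"] >= 85.0)).astype(int)
        + (comp["glucose"] >= 100.0).astype(int)
    )
    keep = n_crit >= 3
    cols = {"sex": sex, "age": age, "height_m": height, "weight_kg": weight,
            "bmi": bmi, "latent_severity": latent, **comp}
    return pd.DataFrame(cols)[keep]


def _nearest_category(hours: np.ndarray, mapping=SEDENTARY_CATEGORY_HOURS) -> np.ndarray:
    mids = np.asarray(mapping, dtype=float)
    edges = (mids[:-1] + mids[1:]) / 2.0
    return np.digitize(hours, edges) + 1


def _ordinal(rng, n, probs, shift_logit=None):
    """Draw an ordinal category 0..K-1 via a shifted latent normal."""
    k = len(probs)
    cum = np.cumsum(probs)[:-1]
    cuts = norm.ppf(cum)
    y = rng.standard_normal(n)
    if shift_logit is not None:
        y = y + shift_logit
    return np.digitize(y, cuts)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate an eligible cohort with all companion tables.

    Eligibility (sex-specific age window, BMI in range, >=3 MetS criteria)
    is enforced by rejection sampling with a cap of 1000 batch rounds;
    an infeasible configuration raises with the observed acceptance rate.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])

    frames = []
    got = 0
    rounds = 0
    while got < spec.n_subjects:
        rounds += 1
        if rounds > 1000:
            rate = got / max(1, rounds * max(64, spec.n_subjects))
            raise RuntimeError(
                "eligibility constraints not satisfiable within 1000 sampling "
                f"rounds (acceptance rate {rate:.2%}); relax thresholds or ranges")
        batch = _draw_eligible(spec, rng, max(64, 2 * (spec.n_subjects - got)))
        frames.append(batch)
        got += len(batch)
    if spec.n_subjects == 0:
        s = _draw_eligible(spec, rng, 0)
    else:
        s = pd.concat(frames, ignore_index=True).iloc[: spec.n_subjects].reset_index(drop=True)
    s.insert(0, "subject_id", [f"S{i + 1:05d}" for i in range(len(s))])

    n = len(s)
    latent = s["latent_severity"].to_numpy()
    # lifestyle couplings act on the tertile of the realized severity score —
    # the stratification the analysis itself uses — so a configured
    # extreme-tertile shift is what the analysed contrast sees
    from .scores import compute_metsss
    severity = compute_metsss(s).to_numpy()
    if n >= 3 and np.ptp(severity) > 0:
        cuts = np.quantile(severity, [1 / 3, 2 / 3], method="inverted_cdf")
        tert = (severity > cuts[0]).astype(int) + (severity > cuts[1]).astype(int)
    else:
        tert = np.digitize(latent, _L_TERTILES)
    s["severity_tertile_true"] = tert

    # --- secondary biochemistry / vitals ------------------------------------
    s["hba1c"] = np.round(5.15 + 0.013 * (s["glucose"] - 100.0)
                          + rng.normal(0, 0.3, n), 2)
    tc = rng.normal(208.0, 36.0, n)
    floor_tc = s["hdl"].to_numpy() + s["tag"].to_numpy() / 5.0 + 30.0
    s["tc"] = np.maximum(tc, floor_tc)
    s["hr"] = rng.normal(69.0, 9.5, n) + 2.2 * latent

    # --- medications (logistic in latent severity) --------------------------
    for med, (b0, b1) in spec.medication_logit.items():
        p = 1.0 / (1.0 + np.exp(-(b0 + b1 * latent)))
        s[med] = rng.random(n) < p

    # --- sociodemographics ---------------------------------------------------
    edu_shift = _tertile_shift(tert, _effect(spec, "education"), 1.0)
    s["education"] = pd.Categorical.from_codes(
        _ordinal(rng, n, [0.49, 0.29, 0.22], -edu_shift),
        ["primary", "secondary", "academic"])
    smoke_shift = _tertile_shift(tert, _effect(spec, "smoking"), 1.0)
    s["smoking"] = pd.Categorical.from_codes(
        _ordinal(rng, n, [0.44, 0.43, 0.13], smoke_shift),
        ["never", "former", "current"])
    mar_shift = _tertile_shift(tert, _effect(spec, "marital"), 1.0)
    s["marital"] = pd.Categorical.from_codes(
        _ordinal(rng, n, [0.13, 0.76, 0.11], mar_shift),
        ["single_divorced", "married", "widowed"])
    emp_shift = _tertile_shift(tert, _effect(spec, "employment"), 1.0)
    s["employment"] = pd.Categorical.from_codes(
        _ordinal(rng, n, [0.20, 0.23, 0.57], emp_shift),
        ["working", "non_working", "retired"])

    # --- sedentary behaviour, sleep, chair stand ----------------------------
    sit = rng.normal(8.0, 2.0, n) + _tertile_shift(tert, _effect(spec, "sedentary"), 2.0)
    tv = rng.normal(5.0, 1.8, n) + _tertile_shift(tert, _effect(spec, "tv"), 1.8)
    comp_h = np.abs(rng.normal(0.8, 1.0, n))
    jour = np.abs(rng.normal(0.9, 0.9, n))
    for name, hours in [("sit_total_cat", sit), ("sit_tv_cat", tv),
                        ("sit_computer_cat", comp_h), ("sit_journeys_cat", jour)]:
        s[name] = _nearest_category(np.clip(hours, 0.0, None))
    s["sleep_weekday"] = np.clip(
        rng.normal(7.0, 1.1, n) + _tertile_shift(tert, _effect(spec, "sleep"), 1.1), 3, 12)
    s["sleep_weekend"] = np.clip(
        rng.normal(7.2, 1.1, n) + _tertile_shift(tert, _effect(spec, "sleep"), 1.1), 3, 12)
    s["chair_stand"] = np.rint(np.clip(
        rng.normal(13.3, 5.0, n) + _tertile_shift(tert, _effect(spec, "chair_stand"), 5.0),
        0, 40)).astype(int)

    # --- missingness flags ---------------------------------------------------
    s["pa_missing"] = rng.random(n) < spec.missing_pa_rate
    s["ffq_missing"] = rng.random(n) < spec.missing_ffq_rate
    cvd_missing = rng.random(n) < spec.missing_cvd_rate
    s.loc[cvd_missing, "hdl"] = np.nan

    # --- activity records (long) ---------------------------------------------
    activity = _generate_activity(s, spec, np.random.default_rng([spec.seed, 1]))
    # --- BDI items (long) ----------------------------------------------------
    bdi = _generate_bdi(s, spec, np.random.default_rng([spec.seed, 2]))
    # --- supplements ----------------------------------------------------------
    supp_rng = np.random.default_rng([spec.seed, 4])
    users = supp_rng.random(n) < spec.supplement_rate
    supplements = pd.DataFrame(
        {"vitamin_c_mg": 60.0, "vitamin_d_ug": 5.0, "vitamin_e_mg": 10.0,
         "vitamin_b9_ug": 200.0, "vitamin_b12_ug": 2.5, "iodine_ug": 100.0,
         "magnesium_mg": 80.0, "zinc_mg": 5.0, "iron_mg": 5.0,
         "selenium_ug": 25.0, "calcium_mg": 120.0},
        index=s["subject_id"])
    supplements.loc[~users, :] = 0.0

    return Cohort(subjects=s, activity=activity, bdi=bdi,
                  supplements=supplements, spec=spec)


# activity class -> (MET score of the representative activity,
#                    weekly MET·min gamma mean, probability of none)
_ACTIVITY_CLASSES = {
    "walking": (3.3, 930.0, 0.15),
    "brisk_walking": (4.5, 1200.0, 0.25),
    "jogging": (7.0, 1250.0, 0.45),
}
_LTPA_EFFECT_KEY = {"walking": "ltpa_light", "brisk_walking": "ltpa_moderate",
                    "jogging": "ltpa_vigorous"}
_GAMMA_SHAPE = 0.9


def _generate_activity(s: pd.DataFrame, spec: CohortSpec,
                       rng: np.random.Generator) -> pd.DataFrame:
    n = len(s)
    tert = s["severity_tertile_true"].to_numpy()
    rows = []
    for code, (met, mean_w, p_zero) in _ACTIVITY_CLASSES.items():
        sd_w = mean_w / np.sqrt(_GAMMA_SHAPE)
        mean_adj = np.maximum(
            mean_w + _tertile_shift(tert, _effect(spec, _LTPA_EFFECT_KEY[code]), sd_w),
            10.0)
        weekly = rng.gamma(_GAMMA_SHAPE, mean_adj / _GAMMA_SHAPE, n)
        weekly[rng.random(n) < p_zero] = 0.0
        days = rng.integers(1, 8, n).astype(float)
        days[weekly == 0] = 0.0
        minutes = np.where(weekly > 0, weekly / (met * np.maximum(days, 1.0)), 0.0)
        rows.append(pd.DataFrame({
            "subject_id": s["subject_id"], "activity_code": code,
            "met_score": met, "days_per_week": days, "minutes_per_day": minutes}))
    act = pd.concat(rows, ignore_index=True)
    act = act[~act["subject_id"].isin(s.loc[s["pa_missing"], "subject_id"])]
    return act.sort_values(["subject_id", "activity_code"], ignore_index=True)


def _generate_bdi(s: pd.DataFrame, spec: CohortSpec,
                  rng: np.random.Generator) -> pd.DataFrame:
    n = len(s)
    tert = s["severity_tertile_true"].to_numpy()
    lam = np.exp(rng.normal(np.log(0.28), 0.75, n))
    # coupling expressed on the total-score scale (SD about 7.4 -> per item /21)
    lam = np.clip(lam + _tertile_shift(tert, _effect(spec, "bdi"), 7.4) / 21.0, 0.005, None)
    items = np.minimum(rng.poisson(lam[:, None], (n, 21)), 3)
    return pd.DataFrame({
        "subject_id": np.repeat(s["subject_id"].to_numpy(), 21),
        "item": np.tile(np.arange(1, 22), n),
        "score": items.ravel(),
    })


# per-item target servings/day by food group (drives the latent-normal mean
# of the nine-level frequency distribution); chosen so food-group totals sit
# near the intake levels typical of older Mediterranean cohorts
_GROUP_ITEM_TARGET = {
    "fruits": 0.145, "vegetables": 0.125, "sofrito": 0.30, "potatoes": 0.145,
    "legumes": 0.09, "refined_cereals": 0.18, "whole_cereals": 0.175,
    "fish_seafood": 0.068, "red_meat": 0.065, "processed_meat": 0.11,
    "white_meat": 0.125, "eggs": 0.20, "dairy": 0.17, "butter_cream": 0.05,
    "nuts": 0.125, "olive_oil": 1.30, "other_oils": 0.10,
    "sweets_pastries": 0.055, "sugary_drinks": 0.035, "snacks": 0.045,
    "wine_beer": 0.31, "spirits": 0.03, "tea": 0.15, "coffee": 1.0,
    "garlic": 0.60, "onion": 0.60,
}

# coupling key applied to each coupled food group
_GROUP_EFFECT_KEY = {"nuts": "nuts", "red_meat": "red_processed_meat",
                     "processed_meat": "red_processed_meat",
                     "other_oils": "other_oils", "spirits": "spirits"}

_FREQ_MIDPOINTS = np.array([0.0, 2 / 30.4, 1 / 7, 3 / 7, 5.5 / 7, 1.0, 2.5, 5.0, 6.0])
_LATENT_CUTS = np.array([0.0, 0.55, 1.1, 1.7, 2.3, 3.0, 3.7, 4.4])


def _solve_latent_mu(target: float) -> float:
    """Latent-normal mean whose implied expected servings/day hits target."""
    lo, hi = -6.0, 8.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        # P(cat <= k) at each cut gives the nine category probabilities
        cdfs = norm.cdf(_LATENT_CUTS - mid)
        probs = np.concatenate((cdfs[:1], np.diff(cdfs), [1.0 - cdfs[-1]]))
        mean = float(probs @ _FREQ_MIDPOINTS)
        if mean < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def generate_ffq_responses(cohort: Cohort, fct: pd.DataFrame | None = None) -> pd.DataFrame:
    """Generate the 143-item FFQ response table for a cohort.

    Every subject without a missing FFQ answers all 143 items with one of the
    nine frequency categories.  Each item's category comes from a latent
    normal (group-level location + a subject appetite factor + noise) binned
    at fixed cut-points; severity-coupled food groups (nuts, red/processed
    meat, other oils, spirits) shift with the subject's latent tertile.

    Returns long format: ``subject_id``, ``item_id``, ``category``,
    ``portion_g``.
    """
    if fct is None:
        fct = default_food_composition()
    spec = cohort.spec
    rng = np.random.default_rng([spec.seed, 3])
    s = cohort.subjects
    answering = s.loc[~s["ffq_missing"]]
    n = len(answering)
    if n == 0:
        return pd.DataFrame(columns=["subject_id", "item_id", "category", "portion_g"])
    tert = answering["severity_tertile_true"].to_numpy()
    appetite = rng.normal(0.0, 0.15, n)

    group_mu = {g: _solve_latent_mu(t) for g, t in _GROUP_ITEM_TARGET.items()}
    item_groups = fct["food_group"].to_numpy()
    mu_items = np.array([group_mu[g] for g in item_groups])
    shift = np.zeros((n, len(fct)))
    for j, g in enumerate(item_groups):
        key = _GROUP_EFFECT_KEY.get(g)
        if key:
            shift[:, j] = _tertile_shift(tert, _effect(spec, key), 1.0)

    y = mu_items[None, :] + appetite[:, None] + shift + rng.standard_normal((n, len(fct)))
    cat_idx = np.digitize(y, _LATENT_CUTS)  # 0..8
    cats = np.asarray(FREQUENCY_CATEGORIES, dtype=object)[cat_idx]

    out = pd.DataFrame({
        "subject_id": np.repeat(answering["subject_id"].to_numpy(), len(fct)),
        "item_id": np.tile(fct.index.to_numpy(), n),
        "category": cats.ravel(),
        "portion_g": np.tile(fct["portion_g"].to_numpy(), n),
    })
    return out
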