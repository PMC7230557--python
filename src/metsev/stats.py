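"""Exclusion cascade, tertile descriptives, group-comparison statistics and
the five report tables.

The analysis layer mirrors a standard baseline-characteristics workflow:
subjects are dropped in a fixed stage order (each counted at its first
failing stage), the severity score is split into tertiles, and every
reported variable is compared across tertiles with a chi-square test
(categorical), Kruskal-Wallis (non-normal continuous) or one-way
ANOVA/ANCOVA (continuous), with Bonferroni-corrected pairwise contrasts.
ANCOVA is a linear model with the tertile as a 3-level factor plus
dummy-coded covariates; the family test is the 2-df F-test on the factor,
and pairwise letters come from the covariate-adjusted contrasts of that
same model with p multiplied by 3 (capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from . import activity as act
from . import dietary, scores
from .synthetic import Cohort

__all__ = [
    "ExclusionFlow",
    "apply_exclusions",
    "standard_exclusion_stages",
    "score_cohort",
    "describe_by_tertile",
    "test_categorical",
    "test_quantitative",
    "test_nonparametric",
    "normality_and_variance_checks",
    "build_tables",
]

SEX_AGE_COVARIATES = ["sex", "age"]
FULL_COVARIATES = ["sex", "age", "education", "smoking", "marital", "employment"]
MEDICATION_COVARIATES = ["med_antihypertensive", "med_cholesterol", "med_insulin",
                         "med_oral_hypoglycaemic", "med_aspirin"]
_CATEGORICAL_COVARIATES = {"sex", "education", "smoking", "marital", "employment",
                           "med_antihypertensive", "med_cholesterol", "med_insulin",
                           "med_oral_hypoglycaemic", "med_aspirin"}


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

@dataclass
class ExclusionFlow:
    """Flow accounting for the staged exclusion cascade."""

    initial_n: int
    stage_counts: dict = field(default_factory=dict)  # stage name -> excluded n
    final_n: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [{"stage": k, "excluded": v} for k, v in self.stage_counts.items()]
        rows.append({"stage": "analysed", "excluded": self.final_n})
        return pd.DataFrame(rows)

    def check(self) -> None:
        assert self.initial_n == sum(self.stage_counts.values()) + self.final_n


def apply_exclusions(cohort: pd.DataFrame, stages) -> tuple[pd.DataFrame, ExclusionFlow]:
    """Apply ordered exclusion stages; each subject is counted once, at the
    first stage whose predicate flags it.

    ``stages`` is an ordered sequence of ``(name, mask)`` pairs where mask is
    a boolean Series aligned with ``cohort`` (True = exclude).  Returns the
    analysed cohort and the per-stage flow.
    """
    flow = ExclusionFlow(initial_n=len(cohort))
    remaining = pd.Series(True, index=cohort.index)
    for name, mask in stages:
        mask = mask.reindex(cohort.index).fillna(False).astype(bool)
        hit = remaining & mask
        flow.stage_counts[name] = int(hit.sum())
        remaining &= ~hit
    flow.final_n = int(remaining.sum())
    flow.check()
    return cohort.loc[remaining], flow


def standard_exclusion_stages(subjects: pd.DataFrame,
                              ltpa: pd.DataFrame,
                              energy: pd.Series) -> list[tuple[str, pd.Series]]:
    """The study's five stages, in order: missing PA questionnaires, total-PA
    outliers (>=3 SD within sex x age band), extreme energy intake, missing
    FFQ, missing cardiovascular-risk information."""
    idx = subjects.index
    missing_pa = subjects.get("pa_missing", pd.Series(False, index=idx)).astype(bool)

    weekly = ltpa["ltpa_weekly"] if "ltpa_weekly" in ltpa else pd.Series(dtype=float)
    weekly = subjects["subject_id"].map(weekly)
    pa_out = act.pa_outlier_filter(weekly, subjects["sex"], subjects["age"])

    e = subjects["subject_id"].map(energy)
    extreme_energy = dietary.energy_exclusion(e.to_numpy(), subjects["sex"].to_numpy())
    extreme_energy.index = idx
    missing_ffq = (subjects.get("ffq_missing", pd.Series(False, index=idx)).astype(bool)
                   | e.isna())
    cvd_cols = ["wc", "sbp", "dbp", "glucose", "tag", "hdl"]
    missing_cvd = subjects[cvd_cols].isna().any(axis=1)
    return [
        ("missing_pa_questionnaires", missing_pa),
        ("pa_outliers", pa_out),
        ("extreme_energy", extreme_energy),
        ("missing_ffq", missing_ffq),
        ("missing_cvd_risk_info", missing_cvd),
    ]


def score_cohort(cohort: Cohort, ffq: pd.DataFrame | None = None,
                 apply_cascade: bool = True):
    """Run the full derived-score pipeline on a generated or loaded cohort.

    Computes nutrient profiles, food groups, DII, MD-17, LTPA summaries,
    sedentary hours, BDI, LDL, VAI, MetSSS and its tertiles, applies the
    standard exclusion cascade and returns ``(scored DataFrame indexed by
    subject_id, ExclusionFlow, tertile cut-points)``.
    """
    s = cohort.subjects.set_index("subject_id", drop=False)
    if ffq is None:
        from .synthetic import generate_ffq_responses
        ffq = generate_ffq_responses(cohort)

    profiles = dietary.compute_nutrient_profiles(ffq, supplements=cohort.supplements)
    groups = dietary.compute_food_groups(ffq)
    ltpa = act.summarize_ltpa(cohort.activity)

    if apply_cascade:
        stages = standard_exclusion_stages(s, ltpa, profiles["energy_kcal"])
        analysed, flow = apply_exclusions(s, stages)
    else:
        analysed, flow = s, ExclusionFlow(initial_n=len(s), final_n=len(s))

    out = analysed.copy()
    out = out.join(profiles, how="left").join(groups, how="left")
    out = out.join(ltpa, how="left")
    # subjects who answered the PA questionnaires but reported no activity
    # are true zeros; missing questionnaires stay missing
    answered = ~out.get("pa_missing", pd.Series(False, index=out.index)).astype(bool)
    for col in ("ltpa_total", "ltpa_light", "ltpa_moderate", "ltpa_vigorous",
                "ltpa_weekly"):
        if col in out.columns:
            out.loc[answered, col] = out.loc[answered, col].fillna(0.0)

    # per-group food intakes feed MD-17 and the DII whole-food parameters
    for g in ("garlic", "tea", "onion"):
        out[f"{g}_g"] = out.get(f"{g}_g", 0.0)
    out["dii"] = dietary.compute_dii(out, method="normal")
    out["md17"] = dietary.score_md17(out)

    out["sedentary_h"] = act.sedentary_hours(out["sit_total_cat"])
    out["tv_h"] = act.sedentary_hours(out["sit_tv_cat"])
    out["sleep_h"] = act.sleep_average(out["sleep_weekday"], out["sleep_weekend"])

    out["bdi"] = scores.bdi_total(cohort.bdi[
        cohort.bdi["subject_id"].isin(out.index)])
    out["ldl"] = scores.friedewald_ldl(out["tc"], out["hdl"], out["tag"])
    out["vai"] = scores.compute_vai(out["sex"].to_numpy(), out["wc"].to_numpy(),
                                    out["bmi"].to_numpy(), out["tag"].to_numpy(),
                                    out["hdl"].to_numpy())
    out["metsss"] = scores.compute_metsss(out)
    out["tertile"], cuts = scores.assign_tertiles(out["metsss"])
    flags = scores.mets_component_flags(out)
    out = out.join(flags)
    return out, flow, cuts


# ---------------------------------------------------------------------------
# Descriptives and tests
# ---------------------------------------------------------------------------

def describe_by_tertile(values: pd.Series, tertiles: pd.Series) -> pd.DataFrame:
    """Per-tertile n, mean, sample SD, median and IQR (Q3-Q1, linear
    interpolation) for a continuous variable; for categoricals, n and %
    within tertile."""
    df = pd.DataFrame({"x": values, "g": tertiles}).dropna(subset=["g"])
    if df["x"].dtype.kind in "fiu":
        rows = []
        for g, grp in df.groupby("g", observed=False):
            x = grp["x"].dropna()
            if len(x) == 0:
                rows.append({"tertile": g, "n": 0, "mean": np.nan, "sd": np.nan,
                             "median": np.nan, "iqr": np.nan})
                continue
            q1, q3 = np.percentile(x, [25, 75])
            rows.append({"tertile": g, "n": len(x), "mean": x.mean(),
                         "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
                         "median": float(np.median(x)), "iqr": float(q3 - q1)})
        return pd.DataFrame(rows).set_index("tertile")
    tab = pd.crosstab(df["x"], df["g"])
    pct = 100.0 * tab / tab.sum(axis=0)
    out = pd.concat({"n": tab, "pct": pct.round(1)}, axis=1)
    return out


def test_categorical(values: pd.Series, tertiles: pd.Series) -> float:
    """Pearson chi-square p-value on the K x 3 contingency table.

    Zero-margin rows (levels absent everywhere) are dropped.
    """
    tab = pd.crosstab(values, tertiles)
    tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return float("nan")
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(p)


def _model_frame(values, tertiles, data, covariates):
    df = pd.DataFrame({"y": pd.to_numeric(values, errors="coerce"),
                       "tertile": tertiles})
    for c in covariates:
        df[c] = data[c]
    return df.dropna()


def _covariate_terms(covariates):
    return [f"C({c})" if c in _CATEGORICAL_COVARIATES else c for c in covariates]


def test_quantitative(values: pd.Series, tertiles: pd.Series,
                      data: pd.DataFrame | None = None,
                      covariates=()) -> dict:
    """ANOVA/ANCOVA comparison of a continuous variable across tertiles.

    With no covariates this is the one-way ANOVA F-test; with covariates, the
    2-df F-test on the tertile factor in an OLS model with the covariates
    (ANCOVA).  Pairwise contrasts (T1-T2, T1-T3, T2-T3) come from the same
    model, Bonferroni x3 (capped at 1).

    Returns ``{"p": family p, "pairwise": {pair: corrected p},
    "flags": {pair: bool}}``.
    """
    covariates = list(covariates)
    df = _model_frame(values, tertiles, data if data is not None else pd.DataFrame(),
                      covariates)
    df["tertile"] = df["tertile"].astype(str)  # first level (T1) is the reference
    terms = ["C(tertile)"] + _covariate_terms(covariates)
    formula = "y ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    # name rank deficiency explicitly rather than letting lstsq mask it
    exog = model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        names = model.exog_names
        _, r = np.linalg.qr(exog)
        dependent = [names[i] for i in range(len(names))
                     if abs(r[i, i]) < 1e-8] if r.shape[0] == len(names) else names
        raise ValueError(f"design matrix is rank deficient; collinear columns: {dependent}")
    fit = model.fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    p_family = float(aov.loc["C(tertile)", "PR(>F)"])

    levels = sorted(df["tertile"].unique())
    ref = levels[0]

    def term(level):
        return f"C(tertile)[T.{level}]"

    pairs = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            constraint = f"{term(b)} = 0" if a == ref else f"{term(b)} - {term(a)} = 0"
            pairs[f"{a}_vs_{b}"] = fit.t_test(constraint).pvalue
    pairwise = {k: float(min(1.0, 3.0 * float(v))) for k, v in pairs.items()}
    flags = {k: (p_family < 0.05 and v < 0.05) for k, v in pairwise.items()}
    return {"p": p_family, "pairwise": pairwise, "flags": flags}


def test_nonparametric(values: pd.Series, tertiles: pd.Series) -> dict:
    """Kruskal-Wallis comparison across tertiles with Bonferroni pairwise.

    Tie-corrected H statistic; all-tied data yield H = 0, p = 1.
    """
    df = pd.DataFrame({"x": values, "g": tertiles}).dropna()
    groups = [g["x"].to_numpy() for _, g in df.groupby("g", observed=True) if len(g)]
    if len(groups) < 2:
        return {"p": float("nan"), "pairwise": {}, "flags": {}}
    if df["x"].nunique() <= 1:  # every value tied: no evidence of difference
        labels = [str(k) for k, g in df.groupby("g", observed=True) if len(g)]
        pairwise = {f"{a}_vs_{b}": 1.0 for i, a in enumerate(labels)
                    for b in labels[i + 1:]}
        return {"p": 1.0, "statistic": 0.0, "pairwise": pairwise,
                "flags": {k: False for k in pairwise}}
    try:
        h, p = sps.kruskal(*groups)
    except ValueError:  # all values identical
        h, p = 0.0, 1.0
    labels = [str(k) for k, g in df.groupby("g", observed=True) if len(g)]
    pairwise = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            try:
                _, pp = sps.kruskal(groups[i], groups[j])
            except ValueError:
                pp = 1.0
            pairwise[f"{labels[i]}_vs_{labels[j]}"] = float(min(1.0, 3.0 * pp))
    flags = {k: (p < 0.05 and v < 0.05) for k, v in pairwise.items()}
    return {"p": float(p), "statistic": float(h), "pairwise": pairwise, "flags": flags}


def normality_and_variance_checks(values: pd.Series, tertiles: pd.Series) -> dict:
    """Normality (estimated-parameter KS, i.e. Lilliefors) of the pooled
    variable and Levene's test (absolute deviations from group means) for
    variance homogeneity across tertiles."""
    df = pd.DataFrame({"x": values, "g": tertiles}).dropna()
    x = df["x"].to_numpy(dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return {"ks_p": float("nan"), "levene_p": float("nan")}
    _, ks_p = lilliefors(x, dist="norm", pvalmethod="table")
    groups = [g["x"].to_numpy() for _, g in df.groupby("g", observed=True) if len(g) > 1]
    if len(groups) >= 2:
        _, lev_p = sps.levene(*groups, center="mean")
    else:
        lev_p = float("nan")
    return {"ks_p": float(ks_p), "levene_p": float(lev_p)}


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

_PAIR_LETTERS = {"T1_vs_T2": "a", "T1_vs_T3": "b", "T2_vs_T3": "c"}


def _fmt_cont(desc: pd.DataFrame, g: str, nd: int = 1) -> tuple[str, str]:
    row = desc.loc[g]
    return (f"{row['mean']:.{nd}f} ± {row['sd']:.{nd}f}",
            f"{row['median']:.{nd}f} ({row['iqr']:.{nd}f})")


def _letters(flags: dict) -> str:
    return ",".join(_PAIR_LETTERS[k] for k, v in flags.items() if v and k in _PAIR_LETTERS)


def _continuous_row(label, col, scored, tertiles, covariate_sets, nd=1):
    desc = describe_by_tertile(scored[col], tertiles)
    unadj = test_quantitative(scored[col], tertiles)
    sexage = test_quantitative(scored[col], tertiles, scored, covariate_sets["sex_age"])
    full = test_quantitative(scored[col], tertiles, scored, covariate_sets["full"])
    row = {"variable": label}
    for g in ("T1", "T2", "T3"):
        ms, md = _fmt_cont(desc, g, nd)
        row[f"{g}_mean_sd"], row[f"{g}_median_iqr"] = ms, md
    row["p_unadjusted"] = round(unadj["p"], 3)
    row["p_sex_age"] = round(sexage["p"], 3)
    row["p_full"] = round(full["p"], 3)
    row["pairwise"] = _letters(full["flags"])
    return row


def build_tables(scored: pd.DataFrame, rounding: int = 1) -> dict[str, pd.DataFrame]:
    """Assemble the five report tables from a scored, analysed cohort.

    Table 1: sociodemographics, MetS components and medication (chi-square;
    Kruskal-Wallis for age).  Table 2: cardiovascular risk factors and BDI
    (ANCOVA; the full covariate set additionally includes the five drug
    classes).  Table 3: physical activity and sedentary behaviour.
    Table 4: energy and nutrients.  Table 5: food groups, DII and MD
    adherence.  Missing variables are skipped.
    """
    t = scored["tertile"]
    covs = {"sex_age": SEX_AGE_COVARIATES, "full": FULL_COVARIATES}
    covs_med = {"sex_age": SEX_AGE_COVARIATES,
                "full": FULL_COVARIATES + MEDICATION_COVARIATES}

    # ---- Table 1: categorical characteristics + age -------------------------
    rows1 = []
    cat_vars = [("Women", scored["sex"] == "female"),
                ("Obesity", scored.get("obesity")),
                ("Education", scored.get("education")),
                ("Smoking", scored.get("smoking")),
                ("Marital status", scored.get("marital")),
                ("Employment", scored.get("employment")),
                ("High blood pressure", scored.get("high_bp")),
                ("Hyperglycaemia", scored.get("hyperglycaemia")),
                ("Hypertriglyceridemia", scored.get("hypertriglyceridemia")),
                ("Low HDL-cholesterol", scored.get("low_hdl")),
                ("Abdominal obesity", scored.get("abdominal_obesity")),
                ("Antihypertensive agents", scored.get("med_antihypertensive")),
                ("Anti-cholesterol agents", scored.get("med_cholesterol")),
                ("Insulin", scored.get("med_insulin")),
                ("Oral hypoglycaemic agents", scored.get("med_oral_hypoglycaemic")),
                ("Aspirin or antiplatelet drugs", scored.get("med_aspirin"))]
    for label, v in cat_vars:
        if v is None:
            continue
        p = test_categorical(v, t)
        counts = pd.crosstab(v, t)
        row = {"variable": label, "p": round(p, 3)}
        for g in ("T1", "T2", "T3"):
            if True in counts.index and g in counts.columns:
                n_true = int(counts.loc[True, g]) if True in counts.index else 0
                tot = int(counts[g].sum())
                row[g] = f"{n_true} ({100 * n_true / tot:.1f})" if tot else ""
            else:
                row[g] = " / ".join(f"{counts.loc[lev, g]}" for lev in counts.index) \
                    if g in counts.columns else ""
        rows1.append(row)
    kw = test_nonparametric(scored["age"], t)
    desc_age = describe_by_tertile(scored["age"], t)
    row = {"variable": "Age, years", "p": round(kw["p"], 3)}
    for g in ("T1", "T2", "T3"):
        row[g] = _fmt_cont(desc_age, g)[0]
    rows1.append(row)
    table1 = pd.DataFrame(rows1)

    # ---- Tables 2-5: continuous rows ----------------------------------------
    def cont_table(var_list, covariate_sets):
        rows = []
        for label, col, nd in var_list:
            if col not in scored.columns or scored[col].isna().all():
                continue
            rows.append(_continuous_row(label, col, scored, t, covariate_sets, nd))
        return pd.DataFrame(rows)

    table2 = cont_table([
        ("Weight, kg", "weight_kg", 1), ("BMI, kg/m2", "bmi", 1),
        ("Waist circumference, cm", "wc", 1), ("Glucose, mg/dL", "glucose", 1),
        ("Glycated haemoglobin, %", "hba1c", 1),
        ("Total cholesterol, mg/dL", "tc", 1), ("HDL-cholesterol, mg/dL", "hdl", 1),
        ("LDL-cholesterol, mg/dL", "ldl", 1), ("Triglycerides, mg/dL", "tag", 1),
        ("Systolic blood pressure, mmHg", "sbp", 1),
        ("Diastolic blood pressure, mmHg", "dbp", 1),
        ("Heart rate, bpm", "hr", 1), ("Visceral adiposity index", "vai", 1),
        ("Beck Depression Inventory-II", "bdi", 1)], covs_med)

    table3 = cont_table([
        ("Sedentary time, h/d", "sedentary_h", 1), ("TV-viewing time, h/d", "tv_h", 1),
        ("Sleeping time, h/d", "sleep_h", 1),
        ("Total LTPA, MET-min/d", "ltpa_total", 1),
        ("Light LTPA, MET-min/d", "ltpa_light", 1),
        ("Moderate LTPA, MET-min/d", "ltpa_moderate", 1),
        ("Vigorous LTPA, MET-min/d", "ltpa_vigorous", 1),
        ("30-s chair stand test, n", "chair_stand", 1)], covs)

    table4 = cont_table([
        ("Total energy, kcal/d", "energy_kcal", 1),
        ("Total fat, %TE", "fat_pct_te", 1),
        ("Carbohydrate, %TE", "carbohydrate_pct_te", 1),
        ("Protein, %TE", "protein_pct_te", 1),
        ("SFA, g/d", "sfa_g", 1), ("MUFA, g/d", "mufa_g", 1),
        ("PUFA, g/d", "pufa_g", 1), ("Trans FA, g/d", "tfa_g", 2),
        ("Linoleic acid, g/d", "linoleic_g", 1), ("w-3 FA, g/d", "omega3_g", 2),
        ("Glycaemic index", "gi", 1), ("Cholesterol, mg/d", "cholesterol_mg", 1),
        ("Fibre, g/d", "fibre_g", 1), ("Alcohol, g/d", "alcohol_g", 1),
        ("Vitamin A, ug/d", "vitamin_a_ug", 1), ("Vitamin B1, mg/d", "vitamin_b1_mg", 1),
        ("Vitamin B2, mg/d", "vitamin_b2_mg", 1), ("Vitamin B3, mg/d", "vitamin_b3_mg", 1),
        ("Vitamin B6, mg/d", "vitamin_b6_mg", 1), ("Vitamin B9, ug/d", "vitamin_b9_ug", 1),
        ("Vitamin B12, ug/d", "vitamin_b12_ug", 1), ("Vitamin C, mg/d", "vitamin_c_mg", 1),
        ("Vitamin D, ug/d", "vitamin_d_ug", 1), ("Vitamin E, mg/d", "vitamin_e_mg", 1),
        ("Calcium, mg/d", "calcium_mg", 1), ("Phosphorus, mg/d", "phosphorus_mg", 1),
        ("Magnesium, mg/d", "magnesium_mg", 1), ("Iron, mg/d", "iron_mg", 1),
        ("Iodine, ug/d", "iodine_ug", 1), ("Potassium, mg/d", "potassium_mg", 1),
        ("Selenium, ug/d", "selenium_ug", 1), ("Zinc, mg/d", "zinc_mg", 1),
        ("Sodium, mg/d", "sodium_mg", 1)], covs)

    table5 = cont_table([
        ("Fruits, g/d", "fruits_g", 1), ("Vegetables, g/d", "vegetables_g", 1),
        ("Potatoes and tubers, g/d", "potatoes_g", 1), ("Legumes, g/d", "legumes_g", 1),
        ("Nuts, g/d", "nuts_g", 1), ("Cereals, g/d", "cereals_g", 1),
        ("Fish and seafood, g/d", "fish_seafood_g", 1),
        ("Total meat, g/d", "total_meat_g", 1),
        ("Red and processed meat, g/d", "red_processed_meat_g", 1),
        ("White meat, g/d", "white_meat_g", 1), ("Eggs, g/d", "eggs_g", 1),
        ("Dairy products, g/d", "dairy_g", 1), ("Olive oil, g/d", "olive_oil_g", 1),
        ("Other oils and fats, g/d", "other_oils_g", 1),
        ("Snacks, g/d", "snacks_g", 1), ("Wine and beer, g/d", "wine_beer_g", 1),
        ("Spirits, g/d", "spirits_g", 1),
        ("Dietary Inflammatory Index", "dii", 1),
        ("Mediterranean Diet Adherence", "md17", 1)], covs)

    return {"table1": table1, "table2": table2, "table3": table3,
            "table4": table4, "table5": table5}
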