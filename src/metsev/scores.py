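"""Cardiometabolic index computation.

* **MetSSS** — continuous metabolic-syndrome severity: per component the
  standardised exceedance above its clinical threshold, truncated at zero,
  aggregated by sum (default) or Euclidean norm.  Zero means every component
  is at or below threshold in the risk direction; HDL contributes when it
  falls *below* its threshold.
* **VAI** — sex-specific visceral adiposity index, calibrated so a healthy
  non-obese reference subject scores 1.
* **Friedewald LDL** — LDL = TC - HDL - TAG/5 (mg/dL), valid for TAG < 400.
* **BDI-II** — 21 items scored 0-3, total 0-63.
* Harmonized MetS component flags (drug treatment counts as meeting the
  criterion) and tertile assignment of the severity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import MET_S_SCALES, MET_S_THRESHOLDS

__all__ = [
    "MetSSSConfig",
    "compute_metsss",
    "assign_tertiles",
    "compute_vai",
    "friedewald_ldl",
    "bdi_total",
    "mets_component_flags",
]

# mg/dL per mmol/L
TAG_MGDL_PER_MMOL = 88.57
CHOL_MGDL_PER_MMOL = 38.67

_COMPONENTS = ("wc", "tag", "hdl", "sbp", "dbp", "glucose")


@dataclass
class MetSSSConfig:
    """Configuration of the severity score.

    ``thresholds`` values are either a scalar or a ``(men, women)`` pair;
    ``scales`` are the per-component standardisation constants (reference
    SDs, same units as the component).  ``direction`` is +1 for
    risk-increasing components and -1 for HDL.  ``aggregation`` is ``"sum"``
    or ``"euclidean"``.  ``medication_rule="none"`` (default) keeps drug
    treatment out of the score; ``"threshold"`` treats a medicated subject's
    component as at least at threshold.
    """

    thresholds: dict = field(default_factory=lambda: dict(MET_S_THRESHOLDS))
    scales: dict = field(default_factory=lambda: dict(MET_S_SCALES))
    directions: dict = field(default_factory=lambda: {
        "wc": 1, "tag": 1, "hdl": -1, "sbp": 1, "dbp": 1, "glucose": 1})
    aggregation: str = "sum"
    medication_rule: str = "none"

    def __post_init__(self):
        if set(self.thresholds) != set(_COMPONENTS):
            raise ValueError(f"thresholds must cover exactly {_COMPONENTS}")
        if any(self.scales[c] <= 0 for c in _COMPONENTS):
            raise ValueError("scales must be positive")
        if self.directions["hdl"] != -1:
            raise ValueError("HDL direction must be -1 (risk when low)")
        if self.aggregation not in ("sum", "euclidean"):
            raise ValueError("aggregation must be 'sum' or 'euclidean'")

    def threshold_for(self, component: str, sex) -> np.ndarray:
        t = self.thresholds[component]
        if isinstance(t, (tuple, list)):
            men, women = t
            sex_arr = np.asarray(sex, dtype=object)
            return np.where(sex_arr == "female", women, men).astype(float)
        return np.full(np.shape(sex) or (1,), float(t))


def compute_metsss(panel: pd.DataFrame, config: MetSSSConfig | None = None) -> pd.Series:
    """Metabolic-syndrome severity score per subject.

    ``panel`` must carry ``sex`` and the six components ``wc``, ``tag``,
    ``hdl``, ``sbp``, ``dbp``, ``glucose`` (mg/dL, cm, mmHg).  Per component
    h_i = max(0, dir_i * (x_i - t_i) / s_i); the score is sum(h_i) or
    sqrt(sum(h_i^2)).  Subjects with any missing component get a missing
    score (they lack complete cardiovascular-risk information).
    """
    config = config or MetSSSConfig()
    h = np.zeros((len(panel), len(_COMPONENTS)))
    missing = np.zeros(len(panel), dtype=bool)
    for j, comp in enumerate(_COMPONENTS):
        x = panel[comp].to_numpy(dtype=float)
        t = config.threshold_for(comp, panel["sex"].to_numpy())
        d = config.directions[comp]
        h[:, j] = np.maximum(0.0, d * (x - t) / config.scales[comp])
        missing |= np.isnan(x)
    if config.aggregation == "sum":
        score = h.sum(axis=1)
    else:
        score = np.sqrt((h ** 2).sum(axis=1))
    score[missing] = np.nan
    return pd.Series(score, index=panel.index, name="metsss")


def assign_tertiles(scores: pd.Series) -> tuple[pd.Series, tuple[float, float]]:
    """Split severity scores into tertiles at the empirical 1/3 and 2/3
    quantiles.

    Cut-points use the inverted-CDF (type-1) sample quantile, so they are
    always observed values.  T1: score <= q1/3; T2: (q1/3, q2/3]; T3: >
    q2/3 (inclusive-left convention at ties).  Missing scores get missing
    tertiles.  Returns the label Series (categories ``T1`` < ``T2`` <
    ``T3``) and the cut-points.
    """
    vals = scores.dropna()
    if len(vals) < 3:
        raise ValueError("need at least 3 non-missing scores for tertiles")
    q1, q2 = np.quantile(vals.to_numpy(), [1.0 / 3.0, 2.0 / 3.0],
                         method="inverted_cdf")
    if vals.nunique() == 1:
        raise ValueError("tertiles undefined for all-identical scores")
    labels = pd.Series(pd.Categorical(
        np.where(scores <= q1, "T1", np.where(scores <= q2, "T2", "T3")),
        categories=["T1", "T2", "T3"], ordered=True), index=scores.index,
        name="tertile")
    labels[scores.isna()] = np.nan
    return labels, (float(q1), float(q2))


def compute_vai(sex, wc_cm, bmi, tag, hdl, units: str = "mg/dL"):
    """Visceral adiposity index.

    Men:   (WC / (39.68 + 1.88 BMI)) x (TAG / 1.03) x (1.31 / HDL)
    Women: (WC / (36.58 + 1.89 BMI)) x (TAG / 0.81) x (1.52 / HDL)

    The lipid reference constants are mmol/L values; ``units="mg/dL"``
    (default, the storage unit) converts TAG and HDL before evaluation,
    ``units="mmol/L"`` uses them as given.  A healthy non-obese reference
    subject scores exactly 1.
    """
    sex_arr = np.asarray(sex, dtype=object)
    wc = np.asarray(wc_cm, dtype=float)
    bmi_a = np.asarray(bmi, dtype=float)
    tag_a = np.asarray(tag, dtype=float)
    hdl_a = np.asarray(hdl, dtype=float)
    if np.nanmin(tag_a, initial=np.inf) <= 0 or np.nanmin(hdl_a, initial=np.inf) <= 0:
        raise ValueError("TAG and HDL must be positive")
    if units == "mg/dL":
        tag_a = tag_a / TAG_MGDL_PER_MMOL
        hdl_a = hdl_a / CHOL_MGDL_PER_MMOL
    elif units != "mmol/L":
        raise ValueError("units must be 'mg/dL' or 'mmol/L'")
    female = sex_arr == "female"
    denom = np.where(female, 36.58 + 1.89 * bmi_a, 39.68 + 1.88 * bmi_a)
    tag_ref = np.where(female, 0.81, 1.03)
    hdl_ref = np.where(female, 1.52, 1.31)
    vai = (wc / denom) * (tag_a / tag_ref) * (hdl_ref / hdl_a)
    if np.ndim(sex) == 0:
        return float(vai)
    return vai


def friedewald_ldl(tc, hdl, tag):
    """LDL cholesterol by the Friedewald formula (all mg/dL).

    LDL = TC - HDL - TAG/5; returns NaN where TAG >= 400 mg/dL (outside the
    formula's validity range).
    """
    tc_a = np.asarray(tc, dtype=float)
    hdl_a = np.asarray(hdl, dtype=float)
    tag_a = np.asarray(tag, dtype=float)
    ldl = tc_a - hdl_a - tag_a / 5.0
    ldl = np.where(tag_a >= 400.0, np.nan, ldl)
    if np.ndim(tc) == 0:
        return float(ldl)
    return ldl


def bdi_total(items) -> int | pd.Series:
    """Total Beck Depression Inventory-II score: sum of 21 items in [0, 3].

    Accepts one subject's 21 item scores, or a long DataFrame with columns
    ``subject_id`` and ``score`` (returns a per-subject Series).
    """
    if isinstance(items, pd.DataFrame):
        counts = items.groupby("subject_id")["score"].count()
        if (counts != 21).any():
            bad = counts[counts != 21].index.tolist()
            raise ValueError(f"subjects without exactly 21 BDI items: {bad[:5]}")
        scores = items["score"].to_numpy(dtype=float)
        if ((scores < 0) | (scores > 3)).any():
            raise ValueError("BDI item scores must be integers in [0, 3]")
        return items.groupby("subject_id")["score"].sum().rename("bdi")
    arr = np.asarray(items, dtype=float)
    if arr.shape != (21,):
        raise ValueError(f"expected 21 BDI items, got shape {arr.shape}")
    if ((arr < 0) | (arr > 3)).any():
        raise ValueError("BDI item scores must be integers in [0, 3]")
    return int(arr.sum())


def mets_component_flags(panel: pd.DataFrame, config: MetSSSConfig | None = None,
                         use_medication: bool = True) -> pd.DataFrame:
    """Harmonized MetS component flags plus the obesity flag.

    A component flag is true when the value strictly exceeds its threshold in
    the risk direction (HDL strictly below), or — per the harmonized
    definition — the corresponding drug class is used (``use_medication``).
    Medication columns, when present: ``med_antihypertensive`` (blood
    pressure), ``med_oral_hypoglycaemic``/``med_insulin`` (glucose),
    ``med_cholesterol`` (TAG and HDL).  Obesity: BMI >= 30.
    """
    config = config or MetSSSConfig()
    sex = panel["sex"].to_numpy()

    def exceeds(comp):
        x = panel[comp].to_numpy(dtype=float)
        t = config.threshold_for(comp, sex)
        raw = (t - x > 0) if config.directions[comp] < 0 else (x - t > 0)
        out = pd.Series(raw, index=panel.index)
        out[np.isnan(x)] = np.nan
        return out

    def med(col):
        if use_medication and col in panel.columns:
            return panel[col].fillna(False).astype(bool)
        return pd.Series(False, index=panel.index)

    flags = pd.DataFrame(index=panel.index)
    flags["high_bp"] = (exceeds("sbp").astype("boolean") |
                        exceeds("dbp").astype("boolean") | med("med_antihypertensive"))
    flags["hyperglycaemia"] = (exceeds("glucose").astype("boolean") |
                               med("med_oral_hypoglycaemic") | med("med_insulin"))
    flags["hypertriglyceridemia"] = exceeds("tag").astype("boolean") | med("med_cholesterol")
    flags["low_hdl"] = exceeds("hdl").astype("boolean")
    flags["abdominal_obesity"] = exceeds("wc").astype("boolean")
    if "bmi" in panel.columns:
        flags["obesity"] = pd.Series(panel["bmi"].to_numpy(dtype=float) >= 30.0,
                                     index=panel.index).astype("boolean")
        flags.loc[panel["bmi"].isna(), "obesity"] = pd.NA
    return flags
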