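"""Physical-activity and sedentary-behaviour derivations.

Leisure-time physical activity (LTPA) records from the Minnesota-REGICOR
short questionnaire carry an activity's compendium MET score, days/week and
minutes/day.  MET·minutes are intensity x duration; activities are classed
as light (<4.0 MET), moderate ([4.0, 6.0) MET) or vigorous (>=6.0 MET).
Sitting-time categories from the Nurses' Health Study instrument map to
hours/day through a configurable 12-level midpoint table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .reference import SEDENTARY_CATEGORY_HOURS

__all__ = [
    "met_minutes",
    "classify_intensity",
    "summarize_ltpa",
    "pa_outlier_filter",
    "sedentary_hours",
    "sleep_average",
]

log = logging.getLogger(__name__)

DEFAULT_AGE_BANDS = (55, 60, 65, 70, 76)  # 5-year bands covering 55-75


def met_minutes(met_score, minutes_per_day, days_per_week):
    """MET·minutes of an activity: weekly = MET x min/day x days/week.

    Returns ``(weekly, daily)`` where daily = weekly / 7.  Accepts scalars or
    arrays.
    """
    met = np.asarray(met_score, dtype=float)
    minutes = np.asarray(minutes_per_day, dtype=float)
    days = np.asarray(days_per_week, dtype=float)
    if (met <= 0).any():
        raise ValueError("met_score must be positive")
    if ((days < 0) | (days > 7)).any():
        raise ValueError("days_per_week must be in [0, 7]")
    if (minutes < 0).any():
        raise ValueError("minutes_per_day must be non-negative")
    weekly = met * minutes * days
    if np.ndim(met_score) == 0 and np.ndim(minutes_per_day) == 0 and np.ndim(days_per_week) == 0:
        return float(weekly), float(weekly) / 7.0
    return weekly, weekly / 7.0


def classify_intensity(met_score):
    """Intensity class of a MET value: light <4.0, moderate [4.0, 6.0),
    vigorous >=6.0.

    The printed class bounds (<4.0, 4-5.5, >=6.0) leave (5.5, 6.0) open;
    moderate is taken as the half-open interval [4.0, 6.0) so the classes
    partition all positive MET values.
    """
    met = np.asarray(met_score, dtype=float)
    if (met <= 0).any():
        raise ValueError("met_score must be positive")
    out = np.where(met < 4.0, "light", np.where(met < 6.0, "moderate", "vigorous"))
    if np.ndim(met_score) == 0:
        return str(out)
    return out


def summarize_ltpa(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject LTPA totals in MET·min/day by intensity class.

    ``records`` is long format with columns ``subject_id``, ``met_score``,
    ``days_per_week``, ``minutes_per_day``.  Returns a DataFrame indexed by
    subject with ``ltpa_total``, ``ltpa_light``, ``ltpa_moderate``,
    ``ltpa_vigorous`` (MET·min/day) and ``ltpa_weekly`` (MET·min/week).
    """
    if records.empty:
        return pd.DataFrame(columns=["ltpa_total", "ltpa_light", "ltpa_moderate",
                                     "ltpa_vigorous", "ltpa_weekly"])
    weekly, daily = met_minutes(records["met_score"], records["minutes_per_day"],
                                records["days_per_week"])
    r = records[["subject_id"]].copy()
    r["daily"] = daily
    r["weekly"] = weekly
    r["intensity"] = classify_intensity(records["met_score"].to_numpy())
    by_class = r.pivot_table(index="subject_id", columns="intensity", values="daily",
                             aggfunc="sum", fill_value=0.0)
    out = pd.DataFrame(index=by_class.index)
    for cls in ("light", "moderate", "vigorous"):
        out[f"ltpa_{cls}"] = by_class.get(cls, 0.0)
    out["ltpa_total"] = out[["ltpa_light", "ltpa_moderate", "ltpa_vigorous"]].sum(axis=1)
    out["ltpa_weekly"] = r.groupby("subject_id")["weekly"].sum()
    return out


def pa_outlier_filter(
    weekly_met_min: pd.Series,
    sex: pd.Series,
    age: pd.Series,
    age_bands=DEFAULT_AGE_BANDS,
) -> pd.Series:
    """Flag total-PA outliers at >=3 SD from the sex x age-band stratum mean.

    Stratum means and SDs are computed once on the pre-filter data (single
    pass).  Strata with zero SD produce no exclusions.  Returns a boolean
    Series aligned with the input, True = exclude; missing totals are never
    flagged here.
    """
    df = pd.DataFrame({"x": weekly_met_min.astype(float), "sex": sex,
                       "band": pd.cut(age, bins=list(age_bands), right=False)})
    exclude = pd.Series(False, index=df.index)
    for _, grp in df.groupby(["sex", "band"], observed=True):
        vals = grp["x"].dropna()
        if len(vals) < 2:
            continue
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            log.info("PA outlier filter: constant stratum, no exclusions")
            continue
        exclude.loc[vals.index] = (vals - mu).abs() >= 3.0 * sd
    return exclude


def sedentary_hours(category, mapping=SEDENTARY_CATEGORY_HOURS):
    """Map a 12-level sitting-time category index (1..12) to hours/day."""
    cat = np.asarray(category)
    valid = ~pd.isna(cat)
    cat_i = np.where(valid, cat, 1).astype(int)
    if ((cat_i < 1) | (cat_i > len(mapping))).any():
        raise ValueError(f"sitting-time category out of range 1..{len(mapping)}")
    hours = np.asarray(mapping, dtype=float)[cat_i - 1]
    hours = np.where(valid, hours, np.nan)
    if np.ndim(category) == 0:
        return float(hours)
    return hours


def sleep_average(weekday_h, weekend_h):
    """Weighted average daily sleep: (5 x weekday + 2 x weekend) / 7."""
    wd = np.asarray(weekday_h, dtype=float)
    we = np.asarray(weekend_h, dtype=float)
    if np.nanmin(wd, initial=0) < 0 or np.nanmin(we, initial=0) < 0:
        raise ValueError("sleep hours must be non-negative")
    avg = (5.0 * wd + 2.0 * we) / 7.0
    if np.ndim(weekday_h) == 0 and np.ndim(weekend_h) == 0:
        return float(avg)
    return avg
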