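"""Schema-validated delimited-text readers/writers and the run configuration.

All tables travel as delimited text (comma by default, tab accepted).
Internal canonical units: mg/dL for lipids and glucose, cm, kg, mmHg,
MET·min/day; columns declared in another unit through the config's ``units``
map are converted on load and the conversion logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .synthetic import Cohort, CohortSpec

__all__ = ["RunConfig", "load_config", "load_cohort", "write_cohort",
           "write_outputs", "UNIT_FACTORS"]

log = logging.getLogger(__name__)

# (column, source unit) -> factor to canonical units
UNIT_FACTORS: dict[tuple[str, str], float] = {
    ("hdl", "mmol/L"): 38.67,
    ("tc", "mmol/L"): 38.67,
    ("ldl", "mmol/L"): 38.67,
    ("tag", "mmol/L"): 88.57,
    ("glucose", "mmol/L"): 18.016,
    ("wc", "m"): 100.0,
    ("height_m", "cm"): 0.01,
}

SUBJECT_REQUIRED = ["subject_id", "sex", "age", "bmi", "wc", "sbp", "dbp",
                    "glucose", "tag", "hdl"]
ACTIVITY_REQUIRED = ["subject_id", "met_score", "days_per_week", "minutes_per_day"]
FFQ_REQUIRED = ["subject_id", "item_id", "category"]
BDI_REQUIRED = ["subject_id", "item", "score"]


class RunConfig(BaseModel):
    """Run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    cohort_dir: str | None = None
    output_dir: str = "out"
    seed: int = 0
    n_subjects: int = 1000
    delimiter: str = ","
    units: dict[str, str] = Field(default_factory=dict)
    descriptive_decimals: int = 1
    pvalue_decimals: int = 3
    mets_thresholds: dict = Field(default_factory=dict)
    dii_table_path: str | None = None
    food_composition_path: str | None = None


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    for key in ("cohort_dir", "dii_table_path", "food_composition_path"):
        p = getattr(cfg, key)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config {key}: {p} does not exist")
    return cfg


def _read(path: Path, required: list[str], delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    errors = [f"missing column {c!r}" for c in required if c not in df.columns]
    if errors:
        raise ValueError(f"{path.name}: " + "; ".join(errors))
    return df


def _convert_units(df: pd.DataFrame, units: dict[str, str]) -> pd.DataFrame:
    for col, unit in units.items():
        key = (col, unit)
        if key not in UNIT_FACTORS:
            raise ValueError(f"no conversion registered for column {col!r} in {unit!r}")
        if col in df.columns:
            df[col] = df[col] * UNIT_FACTORS[key]
            log.info("converted %s from %s (factor %.4g)", col, unit, UNIT_FACTORS[key])
    return df


def load_cohort(directory: str | Path, units: dict[str, str] | None = None,
                delimiter: str = ",") -> Cohort:
    """Load a cohort written by :func:`write_cohort` (or matching its schema).

    Expects ``subjects.csv``, ``activity.csv``, ``ffq.csv``, ``bdi.csv`` and
    optionally ``supplements.csv`` in ``directory``.  Row-level unit
    conversions from the ``units`` map are applied to the subject table.
    """
    d = Path(directory)
    subjects = _read(d / "subjects.csv", SUBJECT_REQUIRED, delimiter)
    subjects = _convert_units(subjects, units or {})
    activity = _read(d / "activity.csv", ACTIVITY_REQUIRED, delimiter)
    bdi = _read(d / "bdi.csv", BDI_REQUIRED, delimiter)
    supp_path = d / "supplements.csv"
    if supp_path.exists():
        supplements = pd.read_csv(supp_path, sep=delimiter).set_index("subject_id")
    else:
        supplements = pd.DataFrame(index=pd.Index(subjects["subject_id"],
                                                  name="subject_id"))
    return Cohort(subjects=subjects, activity=activity, bdi=bdi,
                  supplements=supplements, spec=CohortSpec(n_subjects=len(subjects)))


def load_ffq(directory: str | Path, delimiter: str = ",") -> pd.DataFrame:
    return _read(Path(directory) / "ffq.csv", FFQ_REQUIRED, delimiter)


def write_cohort(cohort: Cohort, ffq: pd.DataFrame, directory: str | Path,
                 delimiter: str = ",") -> None:
    """Write a cohort as delimited text, one file per table (deterministic
    file set; same inputs -> byte-identical outputs)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(d / "subjects.csv", sep=delimiter, index=False)
    cohort.activity.to_csv(d / "activity.csv", sep=delimiter, index=False)
    cohort.bdi.to_csv(d / "bdi.csv", sep=delimiter, index=False)
    cohort.supplements.to_csv(d / "supplements.csv", sep=delimiter)
    ffq.to_csv(d / "ffq.csv", sep=delimiter, index=False)


def write_outputs(tables: dict[str, pd.DataFrame], flow, scored: pd.DataFrame,
                  directory: str | Path, delimiter: str = ",") -> None:
    """Write scored subjects, the exclusion flow and the report tables."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scored.to_csv(d / "scored.csv", sep=delimiter, index=False)
    flow.as_frame().to_csv(d / "exclusion_flow.csv", sep=delimiter, index=False)
    for name, table in tables.items():
        table.to_csv(d / f"{name}.csv", sep=delimiter, index=False)
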