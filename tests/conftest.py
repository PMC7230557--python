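import numpy as np
import pandas as pd
import pytest

from metsev import CohortSpec, generate_cohort, score_cohort
from metsev.reference import NUTRIENT_COLUMNS


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(CohortSpec(n_subjects=1200, seed=11))


@pytest.fixture(scope="session")
def scored(cohort):
    scored, flow, cuts = score_cohort(cohort)
    return scored


@pytest.fixture
def toy_fct():
    """Two-item composition table for hand-checkable dietary arithmetic."""
    rows = []
    for item, group, portion, gi, fat, protein, carb, kcal, iodine in [
        ("food_a", "nuts", 50.0, 0.0, 10.0, 2.0, 0.0, 98.0, 200.0),
        ("food_b", "fruits", 100.0, 50.0, 0.0, 1.0, 10.0, 44.0, 0.0),
    ]:
        row = {c: 0.0 for c in NUTRIENT_COLUMNS}
        row.update(item_id=item, food_group=group, portion_g=portion, gi=gi,
                   fat_g=fat, protein_g=protein, carbohydrate_g=carb,
                   energy_kcal=kcal, iodine_ug=iodine)
        rows.append(row)
    return pd.DataFrame(rows).set_index("item_id")


def responses(subject_id, items_categories):
    return pd.DataFrame(
        [{"subject_id": subject_id, "item_id": i, "category": c}
         for i, c in items_categories]
    )
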