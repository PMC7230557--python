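import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from metsev import (compute_dii, compute_food_groups, compute_nutrient_profiles,
                    energy_exclusion, frequency_to_per_day, paper_format,
                    score_md17)
from metsev.reference import (DEFAULT_MD17_CRITERIA, FREQUENCY_CATEGORIES,
                              default_dii_parameters, default_food_composition)
from conftest import responses


@pytest.mark.parametrize("category, expected", [
    ("never or almost never", 0.0),
    ("1-3 times/month", 2 / 30.4),
    ("1 time/week", 1 / 7),
    ("2-4 times/week", 3 / 7),
    ("5-6 times/week", 5.5 / 7),
    ("1 time/day", 1.0),
    ("2-3 times/day", 2.5),
    ("4-6 times/day", 5.0),
    (">=6 times/day", 6.0),
])
def test_frequency_midpoints(category, expected):
    assert frequency_to_per_day(category) == pytest.approx(expected, abs=1e-12)


def test_weekly_midpoint_display_truncates_not_rounds():
    # 5.5/7 = 0.7857... prints as 0.78 under the truncating convention
    assert paper_format(frequency_to_per_day("5-6 times/week")) == "0.78"
    assert paper_format(0.999) == "0.99"


def test_unknown_category_rejected():
    with pytest.raises(ValueError, match="unknown frequency category"):
        frequency_to_per_day("sometimes")


class TestNutrientProfile:
    def test_hand_arithmetic(self, toy_fct):
        # one item, once per day, 50 g portion: 10 g fat, 2 g protein, 98 kcal
        r = responses("s1", [("food_a", "1 time/day"),
                             ("food_b", "never or almost never")])
        p = compute_nutrient_profiles(r, toy_fct)
        assert p.loc["s1", "fat_g"] == pytest.approx(10.0)
        assert p.loc["s1", "energy_kcal"] == pytest.approx(98.0)
        # fat %TE = 100 * 9*10 / 98 = 91.84
        assert p.loc["s1", "fat_pct_te"] == pytest.approx(100 * 90 / 98, rel=1e-9)

    def test_all_never_gives_zero_profile(self, toy_fct):
        r = responses("s1", [("food_a", "never or almost never"),
                             ("food_b", "never or almost never")])
        p = compute_nutrient_profiles(r, toy_fct)
        assert (p.loc["s1"].drop(["gi"]) == 0).all()

    def test_supplement_additivity(self, toy_fct):
        r = responses("s1", [("food_a", "1 time/day"),
                             ("food_b", "never or almost never")])
        supp = pd.DataFrame({"iodine_ug": [100.0]}, index=pd.Index(["s1"]))
        p = compute_nutrient_profiles(r, toy_fct, supplements=supp)
        assert p.loc["s1", "iodine_ug"] == pytest.approx(300.0)

    def test_profile_additive_over_items(self, toy_fct):
        both = responses("s1", [("food_a", "1 time/day"), ("food_b", "2-3 times/day")])
        only_a = responses("s1", [("food_a", "1 time/day"),
                                  ("food_b", "never or almost never")])
        only_b = responses("s1", [("food_a", "never or almost never"),
                                  ("food_b", "2-3 times/day")])
        cols = ["energy_kcal", "fat_g", "carbohydrate_g", "iodine_ug"]
        total = compute_nutrient_profiles(both, toy_fct).loc["s1", cols]
        parts = (compute_nutrient_profiles(only_a, toy_fct).loc["s1", cols]
                 + compute_nutrient_profiles(only_b, toy_fct).loc["s1", cols])
        assert np.allclose(total, parts)

    def test_unmapped_item_rejected(self, toy_fct):
        r = responses("s1", [("food_z", "1 time/day")])
        with pytest.raises(ValueError, match="food_z"):
            compute_nutrient_profiles(r, toy_fct)

    def test_negative_supplement_rejected(self, toy_fct):
        r = responses("s1", [("food_a", "1 time/day")])
        supp = pd.DataFrame({"iodine_ug": [-1.0]}, index=pd.Index(["s1"]))
        with pytest.raises(ValueError, match="negative supplement"):
            compute_nutrient_profiles(r, toy_fct, supplements=supp)

    def test_gi_is_carbohydrate_weighted(self, toy_fct):
        # only food_b carries carbohydrate, so pooled GI equals food_b's GI
        r = responses("s1", [("food_a", "1 time/day"), ("food_b", "1 time/day")])
        p = compute_nutrient_profiles(r, toy_fct)
        assert p.loc["s1", "gi"] == pytest.approx(50.0)


@pytest.mark.parametrize("sex, energy, excluded", [
    ("female", 450, True),
    ("female", 500, False),
    ("female", 3500, False),
    ("female", 3501, True),
    ("male", 800, False),
    ("male", 799, True),
    ("male", 4000, False),
    ("male", 4001, True),
])
def test_energy_exclusion_boundaries(sex, energy, excluded):
    assert energy_exclusion([energy], [sex]).iloc[0] == excluded


def test_energy_exclusion_idempotent_and_missing_passthrough():
    e = pd.Series([450.0, np.nan, 2000.0])
    s = pd.Series(["female", "male", "male"])
    first = energy_exclusion(e, s)
    assert first.tolist() == [True, False, False]  # NaN handled elsewhere
    assert energy_exclusion(e[~first].to_numpy(), s[~first].to_numpy()).sum() == 0


class TestMD17:
    def _intakes(self, **over):
        # baseline intake meeting every default criterion
        base = dict(olive_oil_g=50, vegetables_serv=2.5, fruits_serv=3.5,
                    red_processed_meat_serv=0.5, butter_cream_serv=0.1,
                    sugary_drinks_serv=0.0, wine_beer_serv=1.2, legumes_serv=0.5,
                    fish_seafood_serv=0.6, sweets_pastries_serv=0.1,
                    nuts_serv=0.6, white_meat_g=80, red_meat_g=40,
                    sofrito_serv=0.4, whole_cereals_g=80, refined_cereals_g=60,
                    snacks_serv=0.2, spirits_serv=0.0)
        base.update(over)
        return base

    def test_maximum_adherence_scores_17(self):
        assert score_md17(self._intakes()) == 17

    def test_no_adherence_scores_0(self):
        worst = self._intakes(olive_oil_g=0, vegetables_serv=0, fruits_serv=0,
                              red_processed_meat_serv=3, butter_cream_serv=2,
                              sugary_drinks_serv=2, wine_beer_serv=0,
                              legumes_serv=0, fish_seafood_serv=0,
                              sweets_pastries_serv=1, nuts_serv=0,
                              white_meat_g=10, red_meat_g=100, sofrito_serv=0,
                              whole_cereals_g=0, refined_cereals_g=100,
                              snacks_serv=2, spirits_serv=1)
        assert score_md17(worst) == 0

    def test_partial_count(self):
        # exactly 5 criteria hold: olive oil (both), vegetables, fruit, wine
        intakes = self._intakes(red_processed_meat_serv=3, butter_cream_serv=2,
                                sugary_drinks_serv=2, legumes_serv=0,
                                fish_seafood_serv=0, sweets_pastries_serv=1,
                                nuts_serv=0, white_meat_g=10, red_meat_g=100,
                                sofrito_serv=0, whole_cereals_g=0,
                                refined_cereals_g=100, snacks_serv=2,
                                spirits_serv=1)
        assert score_md17(intakes) == 5

    def test_criteria_count_enforced(self):
        with pytest.raises(ValueError, match="17"):
            score_md17(self._intakes(), criteria=DEFAULT_MD17_CRITERIA[:10])

    def test_permutation_invariant_and_bounded(self):
        intakes = self._intakes()
        shuffled = list(DEFAULT_MD17_CRITERIA)[::-1]
        assert score_md17(intakes, shuffled) == score_md17(intakes)
        assert 0 <= score_md17(intakes) <= 17


class TestDII:
    def test_zero_at_reference_means(self):
        table = default_dii_parameters()
        profile = {v: m for v, m in zip(table["variable"], table["global_mean"])}
        assert compute_dii(profile) == pytest.approx(0.0, abs=1e-12)

    def test_two_parameter_hand_value(self):
        table = pd.DataFrame({
            "variable": ["a", "b"],
            "global_mean": [10.0, 5.0],
            "global_sd": [2.0, 1.0],
            "effect_score": [0.5, -0.4],
        }, index=pd.Index(["pro", "anti"], name="parameter"))
        # z = +1 and -1: c = +/-0.682689; 0.5*0.682689 + (-0.4)*(-0.682689)
        val = compute_dii({"a": 12.0, "b": 4.0}, table)
        assert val == pytest.approx(0.9 * (2 * norm.cdf(1.0) - 1), rel=1e-9)
        assert val == pytest.approx(0.6144, abs=5e-4)

    def test_magnitude_bounded_by_effect_mass(self):
        table = default_dii_parameters()
        bound = table["effect_score"].abs().sum()
        extreme_hi = {v: m + 50 * s for v, m, s in zip(
            table["variable"], table["global_mean"], table["global_sd"])}
        extreme_lo = {v: max(0.0, m - 50 * s) for v, m, s in zip(
            table["variable"], table["global_mean"], table["global_sd"])}
        assert abs(compute_dii(extreme_hi)) < bound
        assert abs(compute_dii(extreme_lo)) < bound

    def test_monotone_in_proinflammatory_intake(self):
        table = default_dii_parameters()
        profile = {v: m for v, m in zip(table["variable"], table["global_mean"])}
        base = compute_dii(profile, table)
        profile["sfa_g"] += table.loc["sfa", "global_sd"]
        assert compute_dii(profile, table) > base

    def test_missing_parameter_named(self):
        table = default_dii_parameters()
        with pytest.raises(ValueError, match="tea_g"):
            compute_dii({v: 0.0 for v in table["variable"] if v != "tea_g"}, table)

    def test_nonpositive_sd_rejected(self):
        table = default_dii_parameters().copy()
        table.loc["sfa", "global_sd"] = 0.0
        with pytest.raises(ValueError, match="global_sd"):
            compute_dii({v: 1.0 for v in table["variable"]}, table)


def test_food_groups_cover_defaults(cohort):
    from metsev import generate_ffq_responses
    ffq = generate_ffq_responses(cohort)
    groups = compute_food_groups(ffq)
    assert {"nuts_g", "red_processed_meat_g", "olive_oil_g",
            "total_meat_g"} <= set(groups.columns)
    assert (groups.select_dtypes("number") >= 0).all().all()


def test_default_composition_has_143_items():
    fct = default_food_composition()
    assert len(fct) == 143
    assert (fct.select_dtypes("number") >= 0).all().all()
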