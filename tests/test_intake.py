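"""Intake pipeline: composition-table arithmetic, % energy, excessive flag."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sugarintake.composition import FOOD_GROUPS
from sugarintake.intake import (
    IntakeConfig,
    UnresolvedFoodCodeError,
    classify_excessive,
    cohort_intake_table,
    daily_intake,
    intake_summaries,
    mean_daily_intake,
    nutrient_frame,
    percent_energy,
    prevalence_excessive,
)


@pytest.fixture(scope="module")
def nutrients(food_db=None):
    # minimal two-food table: a sugary drink and a plain staple
    return pd.DataFrame(
        {
            "group": ["Sugar-sweetened beverages", "Cereals and potatoes"],
            "energy": [45.0, 168.0],
            "protein": [0.0, 2.5],
            "fat": [0.0, 0.3],
            "saturated_fat": [0.0, 0.1],
            "carbohydrate": [11.2, 37.1],
            "total_sugar": [11.2, 0.0],
            "added_sugar": [10.0, 0.0],
            "free_sugar": [10.0, 0.0],
        },
        index=pd.Index(["SODA", "RICE"], name="food_code"),
    )


class TestDailyIntake:
    def test_proportional_scaling(self, nutrients):
        entries = pd.DataFrame({"food_code": ["SODA"], "amount": [150.0]})
        out = daily_intake(entries, nutrients)
        assert out["free_sugar"] == pytest.approx(15.0)
        assert out["energy"] == pytest.approx(67.5)
        assert out["free_sugar_Sugar-sweetened beverages"] == pytest.approx(15.0)

    def test_empty_day_is_all_zero(self, nutrients):
        out = daily_intake(pd.DataFrame(columns=["food_code", "amount"]), nutrients)
        assert (out == 0).all()

    def test_additivity_of_split_portions(self, nutrients):
        split = pd.DataFrame({"food_code": ["SODA", "SODA"], "amount": [50.0, 50.0]})
        whole = pd.DataFrame({"food_code": ["SODA"], "amount": [100.0]})
        pd.testing.assert_series_equal(
            daily_intake(split, nutrients), daily_intake(whole, nutrients)
        )

    def test_unresolved_code_raises_with_codes(self, nutrients):
        entries = pd.DataFrame({"food_code": ["GONE"], "amount": [10.0]})
        with pytest.raises(UnresolvedFoodCodeError, match="GONE"):
            daily_intake(entries, nutrients)


class TestMeanDailyIntake:
    def test_unweighted_mean_and_symmetry(self):
        days = pd.DataFrame({"free_sugar": [20.0, 30.0, 40.0]}, index=[1, 2, 3])
        assert mean_daily_intake(days)["free_sugar"] == pytest.approx(30.0)
        permuted = days.iloc[[2, 0, 1]]
        assert mean_daily_intake(permuted)["free_sugar"] == pytest.approx(30.0)

    def test_day_weights(self):
        days = pd.DataFrame({"free_sugar": [10.0, 10.0, 40.0]}, index=[1, 2, 3])
        cfg = IntakeConfig(day_weights={1: 5 / 14, 2: 5 / 14, 3: 4 / 14})
        assert mean_daily_intake(days, cfg)["free_sugar"] == pytest.approx(
            (10 * 5 + 10 * 5 + 40 * 4) / 14
        )

    def test_zero_days_is_error(self):
        with pytest.raises(ValueError):
            mean_daily_intake(pd.DataFrame(columns=["free_sugar"]))


class TestPercentEnergyAndClassification:
    @pytest.mark.parametrize(
        "grams, energy, factor, expected",
        [(50.0, 2000.0, 4.0, 10.0), (0.0, 1500.0, 4.0, 0.0),
         (26.8, 1371.0, 4.0, 7.819)],
    )
    def test_percent_energy(self, grams, energy, factor, expected):
        assert percent_energy(grams, energy, factor) == pytest.approx(expected, abs=5e-4)

    def test_non_positive_energy_is_error(self):
        with pytest.raises(ValueError):
            percent_energy(10.0, 0.0, 4.0)

    @pytest.mark.parametrize("pct, expected", [(12.4, True), (6.5, False), (10.0, True)])
    def test_who_threshold_closed_at_10(self, pct, expected):
        assert classify_excessive(pct) is expected

    @given(st.floats(0, 40), st.floats(0, 40))
    @settings(deadline=None)
    def test_classification_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert classify_excessive(lo) <= classify_excessive(hi)


class TestPrevalence:
    def test_published_subgroup_sizes(self):
        summaries = pd.DataFrame({"excessive": [True] * 72 + [False] * 260})
        assert prevalence_excessive(summaries) == 21.7

    @pytest.mark.parametrize("flags, expected", [([False] * 5, 0.0), ([True] * 4, 100.0)])
    def test_degenerate_cohorts(self, flags, expected):
        assert prevalence_excessive(pd.DataFrame({"excessive": flags})) == expected

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError):
            prevalence_excessive(pd.DataFrame({"excessive": []}))


class TestTwoChildOracle:
    """Hand-computed two-child cohort exercises the whole summary path."""

    def test_matches_hand_arithmetic(self, nutrients):
        records = pd.DataFrame(
            [
                ("a", 1, "weekday_school_lunch", "SODA", 100.0),
                ("a", 1, "weekday_school_lunch", "RICE", 200.0),
                ("a", 2, "weekday_school_lunch", "SODA", 300.0),
                ("a", 3, "weekend", "RICE", 100.0),
                ("b", 1, "weekday_school_lunch", "RICE", 400.0),
                ("b", 2, "weekday_school_lunch", "RICE", 400.0),
                ("b", 3, "weekend", "RICE", 400.0),
            ],
            columns=["child_id", "day_index", "day_type", "food_code", "amount"],
        )
        out = intake_summaries(records, nutrients)
        # child a: free sugar days (10, 30, 0) -> 40/3 g/d
        assert out.loc["a", "free_sugar"] == pytest.approx(40.0 / 3.0)
        # child a energy: (45+336, 135, 168)/3 = 228 kcal/d
        assert out.loc["a", "energy"] == pytest.approx((381 + 135 + 168) / 3)
        assert out.loc["b", "free_sugar"] == 0.0
        assert bool(out.loc["b", "excessive"]) is False
        # child a %E: (40/3)*4/228*100 = 23.4 % -> excessive
        assert out.loc["a", "pct_energy_free_sugar"] == pytest.approx(
            (40 / 3) * 4 / 228 * 100
        )
        assert bool(out.loc["a", "excessive"]) is True


class TestCohortProperties:
    def test_group_breakdown_sums_to_total(self, study_summaries):
        group_cols = [f"free_sugar_{g}" for g in FOOD_GROUPS]
        np.testing.assert_allclose(
            study_summaries[group_cols].sum(axis=1),
            study_summaries["free_sugar"],
            atol=1e-9,
        )

    def test_doubling_amounts_doubles_grams_not_pct(self, study, study_summaries):
        records = study.records.copy()
        records["amount"] *= 2.0
        nutrients = nutrient_frame(study.food_items, study.assignments)
        doubled = intake_summaries(records.loc[records.child_id == records.child_id.iloc[0]], nutrients)
        child = doubled.index[0]
        base = study_summaries.loc[child]
        assert doubled.loc[child, "free_sugar"] == pytest.approx(2 * base["free_sugar"])
        assert doubled.loc[child, "energy"] == pytest.approx(2 * base["energy"])
        assert doubled.loc[child, "pct_energy_free_sugar"] == pytest.approx(
            base["pct_energy_free_sugar"]
        )

    def test_cohort_table_degenerate_stratum_omits_test(self, nutrients):
        summaries = pd.DataFrame(
            {
                **{c: [1.0, 1.0] for c in
                   ["free_sugar", "energy"]
                   + [f"free_sugar_{g}" for g in FOOD_GROUPS]
                   + [f"pct_energy_{n}" for n in
                      ("protein", "fat", "saturated_fat", "carbohydrate",
                       "total_sugar", "added_sugar", "free_sugar")]},
                "excessive": [False, False],
            }
        )
        table = cohort_intake_table(summaries)
        assert table["p_value"].isna().all()
        assert (table["sd"] == 0).all()
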