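"""Unit and property tests for the stepwise sugar-assignment engine."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sugarintake.composition import (
    CompositionError,
    CyclicReferenceError,
    FoodItem,
    SaccharideProfile,
    SugarDatabaseBuilder,
    available_carbohydrate,
    build_database,
    dry_weight_adjust,
    monosaccharide_equivalent_adjust,
    sum_saccharides,
    validate_database,
)


def _item(code="X", group="Other foods", carb=50.0, fiber=0.0, water=10.0, **kw):
    return FoodItem(code, code.lower(), group, energy=100.0, carbohydrate=carb,
                    dietary_fiber=fiber, water=water, **kw)


class TestAvailableCarbohydrate:
    @pytest.mark.parametrize(
        "carb, fiber, expected",
        [(10.0, 2.0, 8.0), (75.5, 0.0, 75.5), (1.0, 3.0, 0.0)],
    )
    def test_subtraction_with_floor(self, carb, fiber, expected, caplog):
        with caplog.at_level(logging.WARNING):
            assert available_carbohydrate(_item(carb=carb, fiber=fiber)) == expected
        if fiber > carb:
            assert "clamped" in caplog.text

    def test_missing_carbohydrate_names_food(self):
        with pytest.raises(CompositionError, match="BAD"):
            _item(code="BAD", carb=float("nan"))


class TestSumSaccharides:
    def test_sum_and_zero(self):
        assert sum_saccharides(SaccharideProfile(1, 2, 0, 3, 0, 0)) == 6
        assert sum_saccharides(SaccharideProfile(0, 0, 0, 0, 0, 0)) == 0

    def test_missing_field_is_not_applicable(self):
        assert sum_saccharides(SaccharideProfile(None, 2, 0, 3, 0, 0)) is None

    def test_negative_rejected(self):
        with pytest.raises(CompositionError):
            SaccharideProfile(glucose=-1.0)


class TestAdjustments:
    @pytest.mark.parametrize("value, expected", [(10.0, 9.5), (0.0, 0.0), (4.2, 3.99)])
    def test_monosaccharide_equivalent(self, value, expected):
        assert monosaccharide_equivalent_adjust(value) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(CompositionError):
            monosaccharide_equivalent_adjust(-1.0)

    def test_dry_weight_ratio(self):
        wet = _item(code="WET", water=90.0)
        dry = _item(code="DRY", water=80.0, carb=50.0)
        # ratio (100-80)/(100-90) = 2
        assert dry_weight_adjust(10.0, wet, dry) == pytest.approx(20.0)
        assert dry_weight_adjust(0.0, wet, dry) == 0.0

    def test_equal_water_identity_and_cap(self):
        a = _item(code="A", water=50.0)
        b = _item(code="B", water=50.0, carb=5.0)
        assert dry_weight_adjust(4.0, a, b) == pytest.approx(4.0)
        assert dry_weight_adjust(40.0, a, b) == pytest.approx(5.0)  # capped

    def test_saturated_referred_item_rejected(self):
        with pytest.raises(CompositionError):
            dry_weight_adjust(1.0, _item(water=100.0), _item())


class TestTotalCascade:
    def test_analytical_profile_wins_step_1(self):
        items = [_item(code="A", saccharides=SaccharideProfile(1, 2, 0, 3, 0, 0))]
        a = build_database(items)["A"]
        assert (a.total_sugar, a.total_step) == (6.0, 1)

    def test_no_information_reaches_step_7(self):
        a = build_database([_item(code="A")])["A"]
        assert (a.total_sugar, a.total_step) == (0.0, 7)

    def test_referred_item_equal_dry_weight_step_4(self):
        ref = _item(code="REF", saccharides=SaccharideProfile(1, 2, 0, 3, 0, 0), water=30.0)
        tgt = _item(code="TGT", raw_form_ref="REF", water=30.0)
        a = build_database([ref, tgt])["TGT"]
        assert (a.total_sugar, a.total_step) == (6.0, 4)

    def test_unresolvable_reference_falls_through(self, caplog):
        tgt = _item(code="TGT", raw_form_ref="NOPE")
        with caplog.at_level(logging.WARNING):
            a = build_database([tgt])["TGT"]
        assert a.total_step == 7
        assert "NOPE" in caplog.text

    def test_cycle_raises(self):
        a = _item(code="A", raw_form_ref="B")
        b = _item(code="B", raw_form_ref="A")
        with pytest.raises(CyclicReferenceError):
            build_database([a, b])

    def test_total_capped_at_available_carbohydrate(self):
        item = _item(code="A", carb=5.0, fiber=1.0, literature_total_sugar=50.0)
        a = build_database([item])["A"]
        assert a.total_sugar == pytest.approx(4.0)


class TestAddedFreeCascade:
    def test_whole_fruit_neither_added_nor_free(self):
        fruit = _item(code="F", group="Fruits and vegetables",
                      saccharides=SaccharideProfile(1, 5, 0, 3, 0, 0), no_added_sugar=True)
        a = build_database([fruit])["F"]
        assert (a.added_sugar, a.free_sugar, a.total_sugar) == (0.0, 0.0, 9.0)

    def test_fruit_juice_sugar_is_all_free(self):
        juice = _item(code="J", group="Fruit and vegetable juices",
                      saccharides=SaccharideProfile(2.4, 2.6, 0, 4.6, 0, 0),
                      no_added_sugar=True, is_fruit_juice_or_honey_or_syrup=True)
        a = build_database([juice])["J"]
        assert a.added_sugar == 0.0
        assert a.free_sugar == pytest.approx(9.6)

    def test_plain_milk_lactose_excluded(self):
        milk = _item(code="M", group="Protein rich animal foods", carb=4.8,
                     saccharides=SaccharideProfile(0, 0, 0, 0, 4.8, 0), no_added_sugar=True)
        a = build_database([milk])["M"]
        assert (a.added_sugar, a.free_sugar, a.total_sugar) == (0.0, 0.0, 4.8)

    def test_granulated_sugar_fully_added(self):
        sugar = _item(code="S", group="Sugars and jams", carb=99.5,
                      saccharides=SaccharideProfile(0, 0, 0, 99, 0, 0), all_sugar_added=True)
        a = build_database([sugar])["S"]
        assert a.added_sugar == a.free_sugar == a.total_sugar == pytest.approx(99.0)

    def test_fallback_proportion_configurable(self):
        from sugarintake.composition import RuleSet

        item = _item(code="A", literature_total_sugar=40.0, assume_half_added=True)
        a = build_database([item], RuleSet(fallback_proportion=0.25))["A"]
        assert a.added_sugar == pytest.approx(10.0)
        assert a.free_step == 9

    def test_clamp_emits_warning_and_enforces_chain(self, caplog):
        item = _item(code="A", literature_total_sugar=5.0, added_sugar_label=9.0)
        with caplog.at_level(logging.WARNING):
            a = build_database([item])["A"]
        assert a.added_sugar == a.free_sugar == pytest.approx(5.0)
        assert "clamping" in caplog.text

    def test_recipe_missing_ingredient_is_error(self):
        item = _item(code="A", literature_total_sugar=5.0, recipe=[("GONE", 0.5)])
        with pytest.raises(CompositionError, match="GONE"):
            build_database([item])


class TestEngineOnSyntheticDb:
    def test_no_invariant_violations(self, food_db):
        items, assignments, _ = food_db
        report = validate_database(items, assignments)
        assert report.ok, report.violations

    def test_every_step_fires_at_least_once(self, food_db):
        _, assignments, _ = food_db
        assert {a.total_step for a in assignments.values()} == set(range(1, 8))
        assert {a.free_step for a in assignments.values()} == set(range(1, 12))

    def test_ground_truth_recovered(self, food_db):
        items, assignments, truth = food_db
        for code, a in assignments.items():
            row = truth.loc[code]
            assert a.total_sugar == pytest.approx(row.true_total, abs=1e-9), code
            assert a.added_sugar == pytest.approx(row.true_added, abs=1e-9), code
            assert a.free_sugar == pytest.approx(row.true_free, abs=1e-9), code

    def test_row_order_invariance(self, food_db):
        items, assignments, _ = food_db
        reversed_assignments = build_database(list(reversed(items)))
        for code, a in assignments.items():
            b = reversed_assignments[code]
            assert (a.total_sugar, a.added_sugar, a.free_sugar) == (
                b.total_sugar, b.added_sugar, b.free_sugar
            )
            assert (a.total_step, a.free_step) == (b.total_step, b.free_step)

    def test_idempotent_rerun_bit_exact(self, food_db):
        items, assignments, _ = food_db
        again = build_database(items)
        assert {c: (a.total_sugar, a.added_sugar, a.free_sugar, a.total_step, a.free_step)
                for c, a in assignments.items()} == \
               {c: (a.total_sugar, a.added_sugar, a.free_sugar, a.total_step, a.free_step)
                for c, a in again.items()}

    def test_injected_violation_is_caught(self, food_db):
        items, assignments, _ = food_db
        broken = dict(assignments)
        victim = next(iter(broken))
        import dataclasses

        broken[victim] = dataclasses.replace(
            broken[victim], free_sugar=broken[victim].total_sugar + 5.0
        )
        report = validate_database(items, broken)
        assert any(victim in v and "free sugar exceeds" in v for v in report.violations)

    def test_step_counts_layout(self, food_db):
        items, assignments, _ = food_db
        report = validate_database(items, assignments)
        assert report.total_step_counts.to_numpy().sum() == len(items)
        assert report.free_step_counts.to_numpy().sum() == len(items)
        assert list(report.total_step_counts.columns) == list(range(1, 8))


@given(
    carb=st.floats(0, 100),
    fiber=st.floats(0, 50),
    lit=st.floats(0, 150),
)
@settings(deadline=None, max_examples=200)
def test_property_chain_invariant_holds(carb, fiber, lit):
    """added <= free <= total <= available carbohydrate for any literature value."""
    item = _item(code="A", carb=carb, fiber=min(fiber, carb),
                 literature_total_sugar=lit, assume_half_added=True)
    a = build_database([item])["A"]
    cap = available_carbohydrate(item)
    assert 0 <= a.added_sugar <= a.free_sugar + 1e-9
    assert a.free_sugar <= a.total_sugar + 1e-9
    assert a.total_sugar <= cap + 1e-9
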