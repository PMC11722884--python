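"""Elementary WF arithmetic: scaling, addition, group averaging, composites."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from dietwf import (
    Conversions,
    FoodRecord,
    GroupWeighting,
    ValidationError,
    WFVector,
    cooked_to_dry_mass,
    effective_seafood_mass,
    group_wf,
    jam_wf,
    wf_add,
    wf_scale,
)
from dietwf.model import round_half_away

wf_components = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)
wf_vectors = st.builds(WFVector, wf_components, wf_components, wf_components)


def rec(name, g, b, gr, **kw):
    return FoodRecord(name=name, wf_per_kg=WFVector(g, b, gr), **kw)


class TestWFVector:
    def test_total_is_derived(self):
        v = WFVector(10.0, 5.0, 5.0)
        assert v.total == 20.0

    @pytest.mark.parametrize("bad", [(-1, 0, 0), (0, -2, 0), (0, 0, float("nan"))])
    def test_negative_or_nonfinite_components_rejected(self, bad):
        with pytest.raises(ValidationError):
            WFVector(*bad)

    def test_food_record_validation(self):
        with pytest.raises(ValidationError):
            rec("x", 1, 1, 1, edible_fraction=0.0)
        with pytest.raises(ValidationError):
            rec("x", 1, 1, 1, edible_fraction=1.5)
        with pytest.raises(ValidationError):
            rec("x", 1, 1, 1, kcal_per_100g=-5)
        with pytest.raises(ValidationError):
            rec("x", 1, 1, 1, aquaculture_fraction=1.5)


class TestScaleAndAdd:
    @pytest.mark.parametrize(
        "v,k,expected",
        [
            ((10, 5, 5), 0.0, (0, 0, 0)),
            ((10, 5, 5), 1.0, (10, 5, 5)),
        ],
    )
    def test_scale_basics(self, v, k, expected):
        assert wf_scale(WFVector(*v), k).as_tuple() == pytest.approx(expected)

    def test_scale_red_meat_row(self):
        # a week of red meat: 113 g at (9661, 505, 537) L/kg
        out = wf_scale(WFVector(9661, 505, 537), 0.113)
        assert out.as_tuple() == pytest.approx((1091.7, 57.1, 60.7), abs=0.1)
        assert out.total == pytest.approx(1209.4, abs=0.1)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValidationError):
            wf_scale(WFVector(1, 1, 1), -0.1)

    def test_add(self):
        assert wf_add(WFVector(1, 2, 3), WFVector(0, 0, 0)).as_tuple() == (1, 2, 3)
        assert wf_add(WFVector(1, 2, 3), WFVector(4, 5, 6)).as_tuple() == (5, 7, 9)

    @given(a=wf_vectors, b=wf_vectors, k=st.floats(min_value=0, max_value=1e3))
    @settings(max_examples=100, derandomize=True)
    def test_conservation(self, a, b, k):
        """Totals are conserved under addition and scaling."""
        assert wf_add(a, b).total == pytest.approx(a.total + b.total, rel=1e-12, abs=1e-9)
        assert wf_scale(a, k).total == pytest.approx(k * a.total, rel=1e-12, abs=1e-9)


class TestGroupWF:
    def test_singleton_any_mode(self):
        f = rec("a", 100, 10, 5)
        for weighting in (
            GroupWeighting("simple_mean"),
            GroupWeighting("serving_weighted"),
            GroupWeighting("consumption_weighted"),
        ):
            out = group_wf([(f, 1.0 if weighting.mode != "serving_weighted" else 50.0)], weighting)
            assert out.isclose(f.wf_per_kg, abs_tol=1e-9)

    def test_simple_mean(self):
        out = group_wf(
            [(rec("a", 1000, 0, 0), 1.0), (rec("b", 3000, 0, 0), 1.0)],
            GroupWeighting("simple_mean"),
        )
        assert out.as_tuple() == pytest.approx((2000, 0, 0))

    def test_serving_weighted_cup_equivalents(self):
        # hand oracle: per-serving WFs 0.244*1000 = 244 L and 0.043*5000 = 215 L,
        # mean 229.5 L over mean serving mass 0.1435 kg -> 1599.3 L/kg
        out = group_wf(
            [(rec("milk", 1000, 0, 0), 244.0), (rec("cheese", 5000, 0, 0), 43.0)],
            GroupWeighting("serving_weighted"),
        )
        assert out.green == pytest.approx(229.5 / 0.1435, rel=1e-9)
        assert out.green == pytest.approx(1599.3, abs=0.05)

    def test_consumption_weighted(self):
        out = group_wf(
            [(rec("a", 1000, 0, 0), 0.25), (rec("b", 3000, 0, 0), 0.75)],
            GroupWeighting("consumption_weighted"),
        )
        assert out.green == pytest.approx(2500)

    def test_errors(self):
        with pytest.raises(ValidationError):
            group_wf([], GroupWeighting("simple_mean"))
        with pytest.raises(ValidationError):
            group_wf([(rec("a", 1, 1, 1), 0.0)], GroupWeighting("serving_weighted"))
        with pytest.raises(ValidationError):
            group_wf(
                [(rec("a", 1, 1, 1), 0.3), (rec("b", 1, 1, 1), 0.3)],
                GroupWeighting("consumption_weighted"),
            )

    @given(st.permutations(list(range(5))))
    @settings(max_examples=30, derandomize=True)
    def test_simple_mean_permutation_invariant(self, order):
        foods = [rec(f"f{i}", 100.0 * (i + 1), 10.0 * i, 5.0) for i in range(5)]
        base = group_wf([(f, 1.0) for f in foods], GroupWeighting("simple_mean"))
        perm = group_wf([(foods[i], 1.0) for i in order], GroupWeighting("simple_mean"))
        assert perm.isclose(base, abs_tol=1e-9)

    def test_simple_mean_idempotent_on_identical_members(self):
        f = rec("a", 123.4, 5.6, 7.8)
        out = group_wf([(f, 1.0)] * 4, GroupWeighting("simple_mean"))
        assert out.isclose(f.wf_per_kg, abs_tol=1e-9)

    def test_result_within_member_range_for_simple_mean(self):
        foods = [rec("a", 100, 1, 2), rec("b", 900, 9, 4)]
        out = group_wf([(f, 1.0) for f in foods], GroupWeighting("simple_mean"))
        assert 100 <= out.green <= 900 and 1 <= out.blue <= 9 and 2 <= out.grey <= 4


class TestComposites:
    def test_jam_zero(self):
        assert jam_wf(WFVector(0, 0, 0), WFVector(0, 0, 0)).total == 0

    def test_jam_total_forced_by_fractions(self):
        out = jam_wf(WFVector(1000, 0, 0), WFVector(1000, 0, 0))
        assert out.total == pytest.approx(750.0)

    def test_jam_from_fruit_and_sugar(self):
        out = jam_wf(WFVector(540, 171, 108), WFVector(860, 327, 137))
        assert out.as_tuple() == pytest.approx((533.0, 190.65, 92.6))

    @given(a=wf_vectors, b=wf_vectors, k=st.floats(min_value=0, max_value=100))
    @settings(max_examples=50, derandomize=True)
    def test_jam_linear_in_both_arguments(self, a, b, k):
        scaled = jam_wf(wf_scale(a, k), b)
        direct = wf_add(wf_scale(jam_wf(a, WFVector(0, 0, 0)), k), jam_wf(WFVector(0, 0, 0), b))
        assert scaled.isclose(direct, abs_tol=1e-6)

    @pytest.mark.parametrize("cooked,dry", [(0, 0), (250, 100), (185, 74)])
    def test_cooked_to_dry(self, cooked, dry):
        assert cooked_to_dry_mass(cooked) == pytest.approx(dry)

    @given(st.floats(min_value=0, max_value=1e5))
    @settings(max_examples=50, derandomize=True)
    def test_cooked_dry_round_trip(self, mass):
        conv = Conversions()
        assert cooked_to_dry_mass(mass, conv) * conv.legume_cooked_to_dry == pytest.approx(
            mass, abs=1e-9
        )

    def test_negative_mass_rejected(self):
        with pytest.raises(ValidationError):
            cooked_to_dry_mass(-1)

    @pytest.mark.parametrize(
        "mass,frac,expected", [(640, 0.5, 320), (123, 0.0, 0), (123, 1.0, 123)]
    )
    def test_effective_seafood_mass(self, mass, frac, expected):
        assert effective_seafood_mass(mass, frac) == pytest.approx(expected)

    def test_seafood_fraction_out_of_range(self):
        with pytest.raises(ValidationError):
            effective_seafood_mass(100, 1.2)

    def test_conversion_defaults(self):
        c = Conversions()
        assert (c.legume_cooked_to_dry, c.aquaculture_fraction) == (2.5, 0.5)
        assert (c.jam_fruit_fraction, c.jam_sugar_fraction) == (0.35, 0.40)
        with pytest.raises(ValidationError):
            Conversions(legume_cooked_to_dry=0)


@pytest.mark.parametrize(
    "x,expected", [(0.5, 1), (1.5, 2), (2.4, 2), (-0.5, -1), (-2.6, -3), (0.0, 0)]
)
def test_round_half_away(x, expected):
    assert round_half_away(x) == expected
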