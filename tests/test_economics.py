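"""Cash-flow construction, annuities and forestry stand arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import landfolio as lf
from landfolio.economics import CashflowSeries

DISC = lf.DiscountSpec(d=0.05, horizon=30)


def npv_annuity_oracle(cash, d=0.05, T=30, t0=0.0):
    """Independent annuity oracle: explicit term-by-term discounted sum."""
    q = 1 + d
    npv = sum(c * q ** -(t + 1) for t, c in enumerate(cash)) - t0
    return npv * (q - 1) * q**T / (q**T - 1)


class TestAnnualNetRevenue:
    @pytest.mark.parametrize(
        "crop,expected",
        [("rice", 300 * 3.7 - 744), ("soybean", 404 * 1.7 - 520)],
    )
    def test_point_inputs(self, default_specs, crop, expected):
        _, crops, _ = default_specs
        spec = crops[crop]
        assert lf.annual_net_revenue(spec, spec.price, spec.yield_) == pytest.approx(
            expected
        )

    def test_zero_price_zero_cost(self):
        spec = lf.CropSpec("x", price=0, yield_=5, annual_cost=0)
        assert lf.annual_net_revenue(spec, 0.0, 5.0) == 0.0


class TestAnnuity:
    def test_level_stream_equals_level(self):
        cash = CashflowSeries(np.full(30, 1000.0))
        assert lf.annuity(cash, DISC) == pytest.approx(1000.0)

    @pytest.mark.parametrize("d,T", [(0.01, 5), (0.05, 30), (0.2, 60)])
    def test_level_stream_identity_across_rates(self, d, T):
        disc = lf.DiscountSpec(d=d, horizon=T)
        cash = CashflowSeries(np.full(T, 123.45))
        assert lf.annuity(cash, disc) == pytest.approx(123.45)

    def test_single_first_year_payment(self):
        # 1050 in year 1 discounts to 1000; annuitized over 30y at 5% ~ 65.05
        v = np.zeros(30)
        v[0] = 1050.0
        r = lf.annuity(CashflowSeries(v), DISC)
        assert r == pytest.approx(1000 * 0.05 * 1.05**30 / (1.05**30 - 1), rel=1e-12)
        assert r == pytest.approx(65.05, abs=0.01)

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.lists(st.floats(-1e5, 1e5), min_size=30, max_size=30),
        y=st.lists(st.floats(-1e5, 1e5), min_size=30, max_size=30),
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
    )
    def test_linearity(self, x, y, a, b):
        x, y = np.array(x), np.array(y)
        lhs = lf.annuity(CashflowSeries(a * x + b * y), DISC)
        rhs = a * lf.annuity(CashflowSeries(x), DISC) + b * lf.annuity(
            CashflowSeries(y), DISC
        )
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_zero_discount_limit_is_plain_average(self):
        disc = lf.DiscountSpec(d=0.0, horizon=10)
        cash = CashflowSeries(np.arange(1.0, 11.0))
        assert lf.annuity(cash, disc) == pytest.approx(np.mean(np.arange(1.0, 11.0)))

    def test_agrees_with_explicit_sum_oracle(self):
        rng = np.random.default_rng(7)
        v = rng.normal(500, 2000, 30)
        assert lf.annuity(CashflowSeries(v), DISC) == pytest.approx(
            npv_annuity_oracle(v), rel=1e-12
        )


class TestCropCashflows:
    def test_banana_establishment_charged_at_years_10_and_20(self, default_specs):
        disc, crops, _ = default_specs
        spec = crops["banana"]
        cash = lf.build_cashflows(
            spec, np.full(30, spec.price), np.full(30, spec.yield_), disc
        )
        level = spec.price * spec.yield_ - spec.annual_cost
        deducted = np.flatnonzero(cash.values < level - 1e-9) + 1
        assert list(deducted) == [10, 20]
        assert cash.t0_outlay == 0.0

    def test_cocoa_establishment_charged_at_year_15_only(self, default_specs):
        disc, crops, _ = default_specs
        spec = crops["cocoa"]
        cash = lf.build_cashflows(
            spec, np.full(30, spec.price), np.full(30, spec.yield_), disc
        )
        level = spec.price * spec.yield_ - spec.annual_cost
        assert list(np.flatnonzero(cash.values < level - 1e-9) + 1) == [15]

    def test_annual_crop_is_level(self, default_specs):
        disc, crops, _ = default_specs
        spec = crops["rice"]
        cash = lf.build_cashflows(
            spec, np.full(30, spec.price), np.full(30, spec.yield_), disc
        )
        assert np.allclose(cash.values, cash.values[0])

    def test_cycle_start_timing_adds_t0_outlay(self, default_specs):
        disc, crops, _ = default_specs
        spec = lf.CropSpec(
            "banana",
            price=292,
            yield_=23,
            annual_cost=4745,
            establishment_cost=2835,
            cycle_length=10,
            establishment_timing="cycle_start",
        )
        cash = lf.build_cashflows(
            spec, np.full(30, 292.0), np.full(30, 23.0), disc
        )
        assert cash.t0_outlay == 2835.0

    def test_length_mismatch_is_an_error(self, default_specs):
        disc, crops, _ = default_specs
        with pytest.raises(ValueError, match="length"):
            lf.build_cashflows(crops["rice"], np.ones(10), np.ones(10), disc)

    def test_deterministic_banana_annuity(self, default_specs):
        # oracle: direct 30-term discounted sum of the level net revenue with
        # establishment renewals at years 10 and 20
        disc, crops, _ = default_specs
        spec = crops["banana"]
        cash = lf.build_cashflows(
            spec, np.full(30, spec.price), np.full(30, spec.yield_), disc
        )
        level = spec.price * spec.yield_ - spec.annual_cost
        oracle = [level] * 30
        oracle[9] -= spec.establishment_cost
        oracle[19] -= spec.establishment_cost
        expected = npv_annuity_oracle(oracle)
        assert lf.annuity(cash, disc) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1788.3, abs=0.5)


class TestForestry:
    @pytest.mark.parametrize(
        "dbh,height,expected",
        [(0.20, 8, 0.18), (0.35, 10, 0.67), (0.35, 12, 0.81)],
    )
    def test_tree_volumes_match_management_plan(self, dbh, height, expected):
        assert lf.tree_volume(dbh, height, 0.70) == pytest.approx(expected, abs=0.005)

    def test_unit_cylinder(self):
        assert lf.tree_volume(2 / math.sqrt(math.pi), 1.0, 1.0) == pytest.approx(1.0)

    def test_nonpositive_dimension_is_an_error(self):
        with pytest.raises(ValueError):
            lf.tree_volume(0.0, 8, 0.7)

    def test_stand_removals_match_management_plan(self, default_specs):
        _, _, forestry = default_specs
        assert lf.stand_removals(forestry["balsa"]) == pytest.approx(
            [58.62, 224.40], abs=0.01
        )
        assert lf.stand_removals(forestry["laurel"]) == pytest.approx(
            [58.62, 269.28], abs=0.01
        )

    def test_full_mortality_removes_nothing(self, default_specs):
        _, _, forestry = default_specs
        spec = forestry["balsa"]
        dead = lf.ForestrySpec(
            crop_id="dead",
            density=spec.density,
            mortality=1.0,
            establishment_cost=spec.establishment_cost,
            cycle_length=spec.cycle_length,
            interventions=spec.interventions,
        )
        assert np.allclose(lf.stand_removals(dead), 0.0)

    def test_thinning_sequence_removes_all_surviving_stems(self, default_specs):
        # 50% thinning then 100% final felling clears the stand
        _, _, forestry = default_specs
        spec = forestry["balsa"]
        surviving = spec.density * (1 - spec.mortality)
        per_tree = [
            lf.tree_volume(iv.dbh, iv.height, iv.form_factor)
            for iv in spec.interventions
        ]
        stems = lf.stand_removals(spec) / per_tree
        assert stems.sum() == pytest.approx(surviving)

    def test_laurel_cashflow_years(self, default_specs):
        disc, _, forestry = default_specs
        cash = lf.forestry_cashflows(forestry["laurel"], disc)
        nonzero = set((np.flatnonzero(cash.values) + 1).tolist())
        # interventions at 8/15 per 15-year cycle; replanting at year 15
        assert nonzero == {8, 15, 23, 30}

    def test_balsa_establishment_at_replacement_years(self, default_specs):
        disc, _, forestry = default_specs
        spec = forestry["balsa"]
        zeroed = lf.ForestrySpec(
            crop_id="z",
            density=spec.density,
            mortality=spec.mortality,
            establishment_cost=spec.establishment_cost,
            cycle_length=spec.cycle_length,
            interventions=tuple(
                lf.Intervention(
                    iv.year, iv.dbh, iv.height, iv.form_factor, iv.removal_fraction
                )
                for iv in spec.interventions
            ),
        )
        cash = lf.forestry_cashflows(zeroed, disc)
        # only establishment outflows remain
        assert set((np.flatnonzero(cash.values) + 1).tolist()) == {6, 12, 18, 24}
        assert np.all(cash.values <= 0)

    def test_revenue_allocation_is_volume_proportional(self, default_specs):
        _, _, forestry = default_specs
        spec = forestry["balsa"]
        removed = lf.stand_removals(spec)
        revs = np.array([iv.revenue for iv in spec.interventions])
        assert revs.sum() == pytest.approx(6000.0)
        assert revs / revs.sum() == pytest.approx(removed / removed.sum())

    def test_multiplier_validation(self, default_specs):
        disc, _, forestry = default_specs
        with pytest.raises(ValueError, match="positive"):
            lf.forestry_cashflows(forestry["balsa"], disc, np.zeros(5), np.ones(5))
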