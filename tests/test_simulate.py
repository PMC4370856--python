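"""Bootstrap/MCS distributions, correlations, copula pairing, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import landfolio as lf

DISC = lf.DiscountSpec()


@pytest.fixture(scope="module")
def rescaled(table, default_specs):
    _, crops, _ = default_specs
    return {
        c: lf.rescale_to_current(table[c], crops[c].price, crops[c].yield_)
        for c in table.crops
    }


class TestBootstrap:
    def test_degenerate_series_gives_point_mass(self, default_specs):
        disc, crops, _ = default_specs
        spec = crops["rice"]
        s = lf.CropSeries("rice", [2000, 2001], [300.0, 300.0], [3.7, 3.7])
        d = lf.bootstrap_annuities(spec, s, disc, reps=50, seed=1)
        det = lf.annuity(
            lf.build_cashflows(spec, np.full(30, 300.0), np.full(30, 3.7), disc), disc
        )
        assert d.sd == 0.0
        assert d.mean == pytest.approx(det)

    def test_mean_converges_to_paired_expectation(self, default_specs, rescaled):
        # analytic oracle: E[annuity] = mean over observed years of
        # (price_t * yield_t) - annual cost, because each horizon year is an
        # independent draw from the rescaled years
        disc, crops, _ = default_specs
        spec = crops["rice"]
        s = rescaled["rice"]
        expected = float(np.mean(s.prices * s.yields)) - spec.annual_cost
        d = lf.bootstrap_annuities(spec, s, disc, reps=100_000, seed=5)
        assert d.mean == pytest.approx(expected, rel=0.01)

    def test_scale_equivariance(self, default_specs, rescaled):
        disc, crops, _ = default_specs
        spec = crops["banana"]
        s = rescaled["banana"]
        doubled_spec = lf.CropSpec(
            "banana",
            price=spec.price * 2,
            yield_=spec.yield_,
            annual_cost=spec.annual_cost * 2,
            establishment_cost=spec.establishment_cost * 2,
            cycle_length=spec.cycle_length,
        )
        s2 = lf.CropSeries("banana", s.years, s.prices * 2, s.yields)
        a = lf.bootstrap_annuities(spec, s, disc, reps=200, seed=11)
        b = lf.bootstrap_annuities(doubled_spec, s2, disc, reps=200, seed=11)
        assert b.samples == pytest.approx(2 * a.samples, rel=1e-12)

    def test_seeded_runs_are_bit_reproducible(self, default_specs, rescaled):
        disc, crops, _ = default_specs
        a = lf.bootstrap_annuities(crops["rice"], rescaled["rice"], disc, 100, seed=42)
        b = lf.bootstrap_annuities(crops["rice"], rescaled["rice"], disc, 100, seed=42)
        assert np.array_equal(a.samples, b.samples)

    def test_shared_years_carry_cross_crop_dependence(self, default_specs, rescaled):
        disc, crops, _ = default_specs
        specs = {c: crops[c] for c in ("rice", "soybean")}
        tbl = lf.SeriesTable({c: rescaled[c] for c in specs})
        dists = lf.bootstrap_table(specs, tbl, disc, reps=2000, seed=3)
        rho = np.corrcoef(dists["rice"].samples, dists["soybean"].samples)[0, 1]
        assert rho > 0.3  # annual revenues of the two crops co-move

    def test_too_few_reps_is_an_error(self, default_specs, rescaled):
        disc, crops, _ = default_specs
        with pytest.raises(ValueError):
            lf.bootstrap_annuities(crops["rice"], rescaled["rice"], disc, reps=1)


class TestMonteCarlo:
    def test_zero_cv_collapses_to_deterministic_annuity(self, default_specs):
        disc, crops, _ = default_specs
        spec = crops["organic_banana"]
        d = lf.mcs_annuities(spec, 0.0, 0.0, disc, reps=50, seed=1)
        det = lf.annuity(
            lf.build_cashflows(
                spec, np.full(30, spec.price), np.full(30, spec.yield_), disc
            ),
            disc,
        )
        assert d.sd == pytest.approx(0.0, abs=1e-9)
        assert d.mean == pytest.approx(det)

    def test_low_price_risk_roughly_halves_return_sd(self, table, default_specs):
        disc, crops, _ = default_specs
        spec = crops["organic_banana"]
        raw = lf.series_stats(table["banana"])
        hi = lf.mcs_annuities(
            spec, raw.price_cv, raw.yield_cv, disc, reps=2000, seed=2
        )
        lo = lf.mcs_annuities(
            spec,
            raw.price_cv,
            raw.yield_cv,
            disc,
            reps=2000,
            seed=2,
            price_sd_override=30.0,
            price_sd_reference_mean=raw.price_mean,
        )
        assert 0.5 < lo.sd / hi.sd < 0.72  # ~506/843 on the documented scale

    def test_per_realization_mode_is_wider_than_per_year(self, default_specs):
        disc, crops, _ = default_specs
        spec = crops["organic_banana"]
        a = lf.mcs_annuities(spec, 0.3, 0.1, disc, 2000, seed=4, draw_mode="per_year")
        b = lf.mcs_annuities(
            spec, 0.3, 0.1, disc, 2000, seed=4, draw_mode="per_realization"
        )
        assert b.sd > 2 * a.sd  # no averaging across years in one draw

    def test_negative_cv_rejected(self, default_specs):
        disc, crops, _ = default_specs
        with pytest.raises(ValueError):
            lf.mcs_annuities(crops["organic_banana"], -0.1, 0.2, disc, 10, 1)

    def test_forestry_zero_volatility_is_deterministic(self, default_specs):
        disc, _, forestry = default_specs
        spec = forestry["balsa"]
        calm = lf.ForestrySpec(
            crop_id="balsa",
            density=spec.density,
            mortality=spec.mortality,
            establishment_cost=spec.establishment_cost,
            cycle_length=spec.cycle_length,
            interventions=spec.interventions,
            price_cv=0.0,
            growth_cv=0.0,
        )
        d = lf.mcs_forestry(calm, disc, reps=20, seed=1)
        det = lf.annuity(lf.forestry_cashflows(spec, disc), disc)
        assert d.sd == pytest.approx(0.0, abs=1e-9)
        assert d.mean == pytest.approx(det)

    def test_forestry_cv_scale(self, default_specs):
        # ~10% price x ~10% growth volatility per cycle, averaged over cycles
        disc, _, forestry = default_specs
        d = lf.mcs_forestry(forestry["balsa"], disc, reps=2000, seed=9)
        assert 0.04 < d.cv < 0.20


class TestCorrelations:
    def test_self_correlation_is_one(self, default_specs, rescaled):
        _, crops, _ = default_specs
        rev = lf.simulate.annual_revenue_table(crops, lf.SeriesTable(rescaled))
        cm = lf.empirical_correlations(rev)
        assert np.allclose(np.diag(cm.values), 1.0)

    def test_rice_soybean_revenue_correlation(self, default_specs, rescaled):
        _, crops, _ = default_specs
        rev = lf.simulate.annual_revenue_table(crops, lf.SeriesTable(rescaled))
        cm = lf.empirical_correlations(rev)
        i, j = cm.crop_ids.index("rice"), cm.crop_ids.index("soybean")
        assert cm.values[i, j] == pytest.approx(0.59, abs=0.03)

    def test_cocoa_rice_revenue_correlation(self, default_specs, rescaled):
        _, crops, _ = default_specs
        rev = lf.simulate.annual_revenue_table(crops, lf.SeriesTable(rescaled))
        cm = lf.empirical_correlations(rev)
        i, j = cm.crop_ids.index("cocoa"), cm.crop_ids.index("rice")
        assert cm.values[i, j] == pytest.approx(0.45, abs=0.06)

    def test_zero_variance_input_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            lf.empirical_correlations(
                pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
            )

    def test_reference_matrix_is_psd_and_repair_is_identity(self, ref_corr):
        assert ref_corr.is_psd()
        assert np.array_equal(ref_corr.repaired().values, ref_corr.values)

    def test_nearest_psd_repairs_and_is_gentle(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = lf.nearest_psd(bad)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-12
        assert np.allclose(np.diag(fixed), 1.0)
        # slightly perturbed PSD matrix: repair stays within 0.01 per entry
        base = lf.load_reference_correlations().values
        jittered = base.copy()
        jittered[0, 1] = jittered[1, 0] = base[0, 1] + 0.002
        assert np.abs(lf.nearest_psd(jittered) - jittered).max() < 0.01


class TestCopulaPairing:
    def test_rank_match_achieves_target_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, 500.0, 2000)
        y = rng.normal(1000.0, 800.0, 2000)
        y2 = lf.rank_match(x, y, rho=0.7, seed=1)
        assert np.corrcoef(x, y2)[0, 1] == pytest.approx(0.7, abs=0.05)

    def test_rank_match_preserves_marginals(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = rng.exponential(size=500)
        y2 = lf.rank_match(x, y, rho=-0.5, seed=2)
        assert np.array_equal(np.sort(y2), np.sort(y))


class TestNormalityDiagnostics:
    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(12).normal(100.0, 20.0, 2000)
        _, p = lf.gof_normality(x)
        assert p > 0.01

    def test_bimodal_sample_strongly_rejected(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(-5, 0.5, 1000), rng.normal(5, 0.5, 1000)])
        _, p = lf.gof_normality(x)
        assert p < 1e-6

    def test_too_small_sample_is_an_error(self):
        with pytest.raises(ValueError):
            lf.gof_normality(np.arange(10.0))


class TestReturnDistribution:
    def test_summary_recomputable_from_samples(self):
        d = lf.ReturnDistribution("x", np.array([1.0, 2.0, 3.0, 4.0]))
        assert d.mean == pytest.approx(2.5)
        assert d.sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
        assert d.min == 1.0 and d.max == 4.0
        assert d.cv == pytest.approx(d.sd / d.mean)
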