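"""Causal estimators against closed forms and independent regression oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrpipe.errors import InsufficientInstrumentsError, UndefinedRatioError
from mrpipe.estimators import (
    cochran_q,
    egger,
    ivw,
    likelihood_mr,
    ratio_estimates,
    wald_ratio,
    weighted_median,
    _profile_loglik,
    _weighted_median,
)
from mrpipe.instruments import HarmonizedInstrument

from conftest import make_dataset, random_dataset


class TestWaldRatio:
    def test_arithmetic(self):
        inst = HarmonizedInstrument("rs1", 0.5, 0.01, 0.1, 0.05)
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_null_effect_gives_or_one(self):
        est = wald_ratio(HarmonizedInstrument("rs1", 0.5, 0.01, 0.0, 0.05))
        assert est.beta == 0.0 and est.or_scale == pytest.approx(1.0)

    def test_orientation_invariance(self):
        a = wald_ratio(HarmonizedInstrument("rs1", 0.5, 0.01, 0.1, 0.05))
        b = wald_ratio(HarmonizedInstrument("rs1", -0.5, 0.01, -0.1, 0.05))
        assert a.beta == pytest.approx(b.beta) and a.se == pytest.approx(b.se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(HarmonizedInstrument("rs1", 0.0, 0.01, 0.1, 0.05))


class TestIVW:
    def test_two_identical_instruments(self):
        ds = make_dataset([0.5, 0.5], [0.01, 0.01], [0.1, 0.1], [0.05, 0.05])
        est = ivw(ds, effect_model="fixed")
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1 / np.sqrt(2))
        assert est.q == pytest.approx(0.0, abs=1e-20)

    def test_equal_weight_symmetry(self):
        ds = make_dataset([1.0, 1.0], [0.01, 0.01], [0.1, 0.3], [0.05, 0.05])
        assert ivw(ds, effect_model="fixed").beta == pytest.approx(0.2)

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(50):
            ds = random_dataset(rng, int(rng.integers(3, 13)))
            bx = np.array([i.beta_exp for i in ds.instruments])
            by = np.array([i.beta_out for i in ds.instruments])
            sy = np.array([i.se_out for i in ds.instruments])
            fit = sm.WLS(by, bx, weights=sy**-2).fit()
            est = ivw(ds, effect_model="fixed")
            assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_single_instrument_delegates_to_wald(self):
        inst = HarmonizedInstrument("rs1", 0.5, 0.01, 0.1, 0.05)
        ds = make_dataset([0.5], [0.01], [0.1], [0.05])
        assert ivw(ds).beta == wald_ratio(inst).beta
        assert ivw(ds).se == wald_ratio(inst).se
        assert ivw(ds).method == "wald"

    def test_fixed_se_never_exceeds_random_se(self, rng):
        for _ in range(20):
            ds = random_dataset(rng, 8)
            assert ivw(ds, effect_model="fixed").se <= ivw(ds, effect_model="random").se

    def test_orientation_invariance(self, rng):
        ds = random_dataset(rng, 6)
        flipped = make_dataset(
            [-i.beta_exp for i in ds.instruments],
            [i.se_exp for i in ds.instruments],
            [-i.beta_out for i in ds.instruments],
            [i.se_out for i in ds.instruments],
        )
        assert ivw(ds).beta == pytest.approx(ivw(flipped).beta)


class TestCochranQ:
    def test_identical_ratios_zero_q(self):
        ds = make_dataset([0.5, 0.5, 0.5], [0.01] * 3, [0.1] * 3, [0.05] * 3)
        het = cochran_q(ratio_estimates(ds), 0.2)
        assert het.q == pytest.approx(0.0, abs=1e-20) and het.i2 == 0.0

    def test_closed_form_i2(self):
        # Q = 10 on 5 df -> I2 = 50%
        from mrpipe.meta_power import i_squared
        assert i_squared(10, 5) == pytest.approx(50.0)

    def test_direct_summation_oracle(self, rng):
        ds = random_dataset(rng, 9)
        ratios = ratio_estimates(ds)
        theta = 0.17
        q = sum(r.weight * (r.beta_ratio - theta) ** 2 for r in ratios)
        assert cochran_q(ratios, theta).q == pytest.approx(q, rel=1e-12)

    def test_needs_two_instruments(self):
        ds = make_dataset([0.5], [0.01], [0.1], [0.05])
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q(ratio_estimates(ds), 0.2)


class TestEgger:
    def test_exact_linear_fit_recovered(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        by = 0.05 + 0.3 * bx
        ds = make_dataset(bx, [0.01] * 4, by, [0.02] * 4)
        est = egger(ds)
        assert est.beta == pytest.approx(0.3)
        assert est.egger_intercept == pytest.approx(0.05)
        assert est.q == pytest.approx(0.0, abs=1e-18)

    def test_no_intercept_data_slope_equals_ivw(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        ds = make_dataset(bx, [0.01] * 4, 0.3 * bx, [0.02] * 4)
        assert egger(ds).beta == pytest.approx(ivw(ds, effect_model="fixed").beta)

    def test_matches_wls_with_intercept_oracle(self, rng):
        for _ in range(50):
            ds = random_dataset(rng, 8)
            bx = np.array([abs(i.beta_exp) for i in ds.instruments])
            by = np.array([np.sign(i.beta_exp) * i.beta_out for i in ds.instruments])
            sy = np.array([i.se_out for i in ds.instruments])
            fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2).fit()
            est = egger(ds)
            assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
            assert est.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert est.se == pytest.approx(fit.bse[1], abs=1e-10)
            assert est.egger_intercept_se == pytest.approx(fit.bse[0], abs=1e-10)

    def test_bootstrap_se_close_to_analytic_when_well_behaved(self, rng):
        # residual dispersion is 1 by construction, so the parametric
        # bootstrap and the analytic WLS standard error estimate the same
        # sampling variability
        j = 40
        bx = rng.uniform(0.05, 0.3, j)
        by = 0.01 + 0.25 * bx + rng.normal(0, 0.02, j)
        ds = make_dataset(bx, [1e-4] * j, by, [0.02] * j)
        analytic = egger(ds, se_method="analytic")
        boot = egger(ds, se_method="bootstrap", n_boot=4000, seed=7)
        # put both on the unit-dispersion scale: the bootstrap resamples from
        # N(beta, se) so it estimates the dispersion-1 sampling SD
        se_unit = analytic.se * np.sqrt((j - 2) / analytic.q)
        assert boot.se == pytest.approx(se_unit, rel=0.15)
        assert boot.beta == analytic.beta

    def test_insufficient_instruments(self):
        ds = make_dataset([0.5, 0.4], [0.01] * 2, [0.1, 0.1], [0.05] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(ds)


class TestWeightedMedian:
    def test_equal_weight_median_identity(self):
        ds = make_dataset([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.9], [0.05] * 3)
        est = weighted_median(ds, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_dominant_instrument_controls_estimate(self):
        # middle-weight SNP holds ~96% of total weight
        ds = make_dataset([1, 1, 1], [0.01] * 3, [0.1, 0.5, 0.9], [0.25, 0.05, 0.25])
        est = weighted_median(ds, n_boot=100, seed=1)
        assert abs(est.beta - 0.5) < 0.05

    def test_interpolation_formula_direct(self):
        b = np.array([0.1, 0.2, 0.4])
        w = np.array([1.0, 2.0, 1.0])
        # cumulative midpoints: 0.125, 0.5, 0.875 -> p=0.5 hits 0.2 exactly
        assert _weighted_median(b, w) == pytest.approx(0.2)
        # asymmetric weights: interpolate between midpoints
        w2 = np.array([2.0, 1.0, 1.0])
        p = np.cumsum(w2 / 4) - w2 / 8  # 0.25, 0.625, 0.875
        expect = 0.1 + (0.5 - 0.25) / (0.625 - 0.25) * 0.1
        assert _weighted_median(b, w2) == pytest.approx(expect)

    def test_needs_three_instruments(self):
        ds = make_dataset([1, 1], [0.01] * 2, [0.1, 0.2], [0.05] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(ds, seed=1)


class TestLikelihoodMR:
    def test_noiseless_proportional_data(self):
        bx = np.array([0.1, 0.2, 0.3])
        ds = make_dataset(bx, [1e-6] * 3, 0.25 * bx, [1e-6] * 3)
        assert likelihood_mr(ds).beta == pytest.approx(0.25, abs=1e-6)

    def test_tiny_exposure_se_limit_matches_ivw(self, rng):
        ds = random_dataset(rng, 7)
        tiny = make_dataset(
            [i.beta_exp for i in ds.instruments],
            [i.se_exp * 1e-6 for i in ds.instruments],
            [i.beta_out for i in ds.instruments],
            [i.se_out for i in ds.instruments],
        )
        assert likelihood_mr(tiny).beta == pytest.approx(
            ivw(ds, effect_model="fixed").beta, abs=1e-5
        )

    def test_profile_maximum_matches_grid_oracle(self, rng):
        ds = random_dataset(rng, 8)
        bx = np.array([i.beta_exp for i in ds.instruments])
        sx = np.array([i.se_exp for i in ds.instruments])
        by = np.array([i.beta_out for i in ds.instruments])
        sy = np.array([i.se_out for i in ds.instruments])
        grid = np.linspace(-2, 2, 400_001)
        ll = [_profile_loglik(t, bx, sx, by, sy) for t in grid[::1000]]
        coarse = grid[::1000][int(np.argmax(ll))]
        fine = np.linspace(coarse - 0.02, coarse + 0.02, 40_001)
        llf = [_profile_loglik(t, bx, sx, by, sy) for t in fine]
        oracle = fine[int(np.argmax(llf))]
        assert likelihood_mr(ds).beta == pytest.approx(oracle, abs=1e-6)

    def test_needs_two_instruments(self):
        ds = make_dataset([0.5], [0.01], [0.1], [0.05])
        with pytest.raises(InsufficientInstrumentsError):
            likelihood_mr(ds)
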