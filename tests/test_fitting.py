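import math

import numpy as np
import pytest

from fermkin import (
    FitConfig,
    KineticParameters,
    NoiseSpec,
    TimeCourse,
    WT_PARAMS,
    fit_biomass,
    fit_full,
    fit_product,
    fit_sugar,
    generate,
    goodness_of_fit,
    logistic_biomass,
    biomass_integral,
)
from fermkin.errors import (
    DegenerateDataError,
    DegenerateStatisticError,
    MissingResponseError,
    UnderdeterminedError,
)

from ._oracles import logistic_sse_grid

FAST = FitConfig(n_starts=3, seed=0)


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        obs = [1.0, 2.0, 3.0, 4.0]
        r2, f, sse, sst = goodness_of_fit(obs, obs, n_params=1)
        assert r2 == 1.0
        assert math.isinf(f)
        assert sse == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.full(4, obs.mean())
        r2, _, sse, sst = goodness_of_fit(obs, pred, n_params=1)
        assert r2 == pytest.approx(0.0, abs=1e-15)
        assert sse == pytest.approx(sst)

    def test_hand_computed_example(self):
        # SSE = .01+.01+.04+.04 = 0.10; SST = 5.0; R2 = 0.98
        # F = ((5.0-0.1)/1) / (0.1/(4-1-1)) = 4.9/0.05 = 98
        r2, f, sse, sst = goodness_of_fit(
            [1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8], n_params=1
        )
        assert sse == pytest.approx(0.10)
        assert sst == pytest.approx(5.0)
        assert r2 == pytest.approx(0.98)
        assert f == pytest.approx(98.0)

    def test_constant_observations_raise(self):
        with pytest.raises(DegenerateStatisticError):
            goodness_of_fit([2, 2, 2, 2], [2, 2, 2, 2.1], n_params=1)

    def test_too_few_points_raise(self):
        with pytest.raises(UnderdeterminedError):
            goodness_of_fit([1, 2, 3], [1, 2, 3], n_params=2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1, 2, 3], [1, 2], n_params=1)


class TestFitBiomass:
    def test_noiseless_recovery(self, noiseless_wt_daily):
        res = fit_biomass(noiseless_wt_daily, FAST)
        assert res.converged
        assert res.params.mu_max == pytest.approx(0.45, rel=1e-4)
        assert res.params.X_max == pytest.approx(9.41, rel=1e-4)
        assert res.params.X0 == pytest.approx(0.5, rel=1e-4)
        assert res.r2["X"] == pytest.approx(1.0, abs=1e-9)

    def test_too_few_distinct_times(self):
        tc = TimeCourse(times=[0.0, 1.0, 2.0], X=[0.5, 1.0, 2.0])
        with pytest.raises(UnderdeterminedError):
            fit_biomass(tc, FAST)

    def test_constant_biomass_is_degenerate(self):
        tc = TimeCourse(times=[0.0, 2.0, 4.0, 6.0, 8.0], X=[3.0] * 5)
        with pytest.raises(DegenerateDataError):
            fit_biomass(tc, FAST)

    def test_grid_search_oracle(self):
        """Brute-force SSE lattice agrees with the optimizer's minimum."""
        p = KineticParameters(mu_max=0.6, X_max=8.0, X0=0.4)
        t = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
        tc = TimeCourse(times=t, X=logistic_biomass(t, p))
        res = fit_biomass(tc, FitConfig(n_starts=3, seed=0, fix={"X0": 0.4}))

        mu_grid = np.linspace(0.3, 0.9, 200)
        xmax_grid = np.linspace(4.0, 12.0, 200)
        sse = logistic_sse_grid(t, tc.X, 0.4, mu_grid, xmax_grid)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        # optimizer must do at least as well as the lattice, and land in the
        # same neighborhood as the lattice minimizer
        assert res.sse["X"] <= sse[i, j] + 1e-12
        assert abs(res.params.mu_max - mu_grid[i]) <= 2 * (mu_grid[1] - mu_grid[0])
        assert abs(res.params.X_max - xmax_grid[j]) <= 2 * (xmax_grid[1] - xmax_grid[0])

    def test_doubling_starts_never_worse(self):
        noisy = generate(
            WT_PARAMS, np.arange(0.0, 13.0, 2.0),
            NoiseSpec(kind="proportional", sd=0.08, n_replicates=3, seed=7),
        )
        sse_few = fit_biomass(noisy, FitConfig(n_starts=4, seed=3)).sse["X"]
        sse_many = fit_biomass(noisy, FitConfig(n_starts=8, seed=3)).sse["X"]
        assert sse_many <= sse_few + 1e-12

    def test_same_seed_reproducible(self, noiseless_wt_daily):
        r1 = fit_biomass(noiseless_wt_daily, FitConfig(n_starts=5, seed=11))
        r2 = fit_biomass(noiseless_wt_daily, FitConfig(n_starts=5, seed=11))
        assert r1.params == r2.params


class TestFitProduct:
    def test_noiseless_recovery_wt(self, noiseless_wt_daily, wt_params):
        growth = KineticParameters(mu_max=0.45, X_max=9.41, X0=0.5)
        res = fit_product(noiseless_wt_daily, growth, FAST)
        assert res.params.alpha == pytest.approx(0.015, rel=1e-6)
        assert res.params.beta < 1e-6

    def test_constant_product(self):
        t = np.arange(0.0, 13.0)
        growth = KineticParameters(mu_max=0.45, X_max=9.41, X0=0.5)
        tc = TimeCourse(times=t, X=logistic_biomass(t, growth), P=np.full(t.size, 0.2))
        res = fit_product(tc, growth, FAST)
        assert res.params.alpha == pytest.approx(0.0, abs=1e-12)
        assert res.params.beta == pytest.approx(0.0, abs=1e-12)

    def test_missing_response(self, wt_params, daily_times):
        tc = TimeCourse(times=daily_times, X=logistic_biomass(daily_times, wt_params))
        with pytest.raises(MissingResponseError):
            fit_product(tc, wt_params, FAST)

    def test_normal_equations_oracle(self):
        """With both coefficients interior, NNLS equals plain least squares."""
        p = KineticParameters(mu_max=0.5, X_max=9.0, alpha=0.03, beta=0.02,
                              X0=0.5, P0=0.0)
        t = np.linspace(0.0, 12.0, 25)
        from fermkin import product_titer

        tc = TimeCourse(times=t, X=logistic_biomass(t, p), P=product_titer(t, p))
        res = fit_product(tc, p, FAST)
        a = np.column_stack([logistic_biomass(t, p) - p.X0, biomass_integral(t, p)])
        expected, *_ = np.linalg.lstsq(a, tc.P - p.P0, rcond=None)
        assert res.params.alpha == pytest.approx(expected[0], rel=1e-8)
        assert res.params.beta == pytest.approx(expected[1], rel=1e-8)
        assert res.params.alpha == pytest.approx(0.03, rel=1e-8)
        assert res.params.beta == pytest.approx(0.02, rel=1e-8)


class TestFitSugar:
    def test_noiseless_recovery(self, noiseless_wt_daily):
        growth = KineticParameters(mu_max=0.45, X_max=9.41, X0=0.5)
        res = fit_sugar(noiseless_wt_daily, growth, FAST)
        assert res.params.Y_XS == pytest.approx(0.63, rel=1e-6)
        assert res.params.M_s == pytest.approx(0.12, rel=1e-6)

    def test_unidentifiable_flat_culture(self):
        t = np.arange(0.0, 13.0)
        growth = KineticParameters(mu_max=0.0, X_max=3.0, X0=3.0, M_s=0.0)
        tc = TimeCourse(times=t, X=np.full(t.size, 3.0), S=np.full(t.size, 20.0))
        # biomass constant and sugar constant: M_s pinned to 0 but Y_XS free
        with pytest.raises(DegenerateDataError):
            fit_sugar(tc, growth, FAST)

    def test_linear_regression_oracle(self):
        p = KineticParameters(mu_max=0.5, X_max=9.0, Y_XS=0.7, M_s=0.1,
                              X0=0.5, S0=40.0)
        t = np.linspace(0.0, 12.0, 25)
        from fermkin import sugar_residual

        tc = TimeCourse(times=t, X=logistic_biomass(t, p), S=sugar_residual(t, p))
        res = fit_sugar(tc, p, FAST)
        a = np.column_stack([logistic_biomass(t, p) - p.X0, biomass_integral(t, p)])
        expected, *_ = np.linalg.lstsq(a, p.S0 - tc.S, rcond=None)
        assert 1.0 / res.params.Y_XS == pytest.approx(expected[0], rel=1e-8)
        assert res.params.M_s == pytest.approx(expected[1], rel=1e-8)


class TestFitFull:
    def test_noiseless_recovery_all_six(self, noiseless_wt_daily):
        res = fit_full(noiseless_wt_daily, FAST)
        p = res.params
        assert p.mu_max == pytest.approx(0.45, rel=1e-3)
        assert p.X_max == pytest.approx(9.41, rel=1e-3)
        assert p.alpha == pytest.approx(0.015, rel=1e-3)
        assert p.beta == pytest.approx(0.0, abs=1e-6)
        assert p.Y_XS == pytest.approx(0.63, rel=1e-3)
        assert p.M_s == pytest.approx(0.12, rel=1e-3)
        assert res.r2["pooled"] == pytest.approx(1.0, abs=1e-9)
        # noiseless analogue of the published fit quality: R2 -> 1, SSE -> 0
        for k in ("X", "S", "P"):
            assert res.r2[k] == pytest.approx(1.0, abs=1e-9)
            assert res.sse[k] == pytest.approx(0.0, abs=1e-9)
            assert math.isfinite(res.f_value[k]) is False or res.f_value[k] > 1e6

    def test_partial_data_contract(self, wt_params, daily_times):
        from fermkin import sugar_residual

        tc = TimeCourse(
            times=daily_times,
            X=logistic_biomass(daily_times, wt_params),
            S=sugar_residual(daily_times, wt_params),
        )
        res = fit_full(tc, FAST)
        assert "P" not in res.r2
        assert set(res.sse) == {"X", "S"}

    def test_biomass_required(self, daily_times, wt_params):
        from fermkin import product_titer

        tc = TimeCourse(times=daily_times, P=product_titer(daily_times, wt_params))
        with pytest.raises(MissingResponseError):
            fit_full(tc, FAST)

    def test_joint_matches_sequential_noiseless(self, noiseless_wt_daily):
        seq = fit_full(noiseless_wt_daily, FitConfig(strategy="sequential", n_starts=3))
        joint = fit_full(noiseless_wt_daily, FitConfig(strategy="joint", n_starts=3))
        for name in ("mu_max", "X_max", "alpha", "Y_XS", "M_s"):
            assert getattr(joint.params, name) == pytest.approx(
                getattr(seq.params, name), rel=1e-3
            ), name
        assert abs(joint.params.beta - seq.params.beta) < 1e-3

    def test_replicates_pooled(self, wt_params):
        tc = generate(
            wt_params, np.arange(0.0, 13.0, 2.0),
            NoiseSpec(kind="none", n_replicates=3),
        )
        res = fit_full(tc, FAST)
        assert res.n_obs["X"] == 21
        assert res.params.mu_max == pytest.approx(0.45, rel=1e-3)


class TestRecoveryProperty:
    def test_random_parameter_recovery(self):
        """50 random sets within +/-50% of the WT reference, noiseless."""
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 13.0)
        base = WT_PARAMS
        failures = []
        for i in range(50):
            p = KineticParameters(
                mu_max=base.mu_max * rng.uniform(0.5, 1.5),
                X_max=base.X_max * rng.uniform(0.5, 1.5),
                alpha=base.alpha * rng.uniform(0.5, 1.5),
                beta=rng.uniform(0.0, 0.01),
                Y_XS=base.Y_XS * rng.uniform(0.5, 1.5),
                M_s=base.M_s * rng.uniform(0.5, 1.5),
                X0=0.5, S0=35.0, P0=0.0,
            )
            tc = generate(p, t, NoiseSpec(kind="none"))
            res = fit_full(tc, FitConfig(n_starts=2, seed=i))
            for name in ("mu_max", "X_max", "alpha", "beta", "Y_XS", "M_s"):
                true, got = getattr(p, name), getattr(res.params, name)
                tol = 1e-3 * max(abs(true), 1e-3)
                if abs(got - true) > tol:
                    failures.append((i, name, true, got))
        assert not failures, failures[:5]

    def test_noise_robustness_small(self):
        """Quick version of the noise-robustness property (20 seeds)."""
        t = np.arange(0.0, 13.0, 2.0)
        errs = []
        for seed in range(20):
            tc = generate(
                WT_PARAMS, t,
                NoiseSpec(kind="proportional", sd=0.05, n_replicates=3, seed=seed),
            )
            res = fit_biomass(tc, FitConfig(n_starts=4, seed=seed))
            errs.append(abs(res.params.mu_max - 0.45) / 0.45)
        assert np.median(errs) < 0.10
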