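"""Grid chi-square fitting, Monte Carlo errors and order parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import truncnorm

from masdyn.spin_sim import (DipolarTensor, PowderScheme, PulseTiming,
                             RedorCurve, methyl_rigid_limit, simulate_redor)
from masdyn.tensor_fit import (PAPER_GRID, SimulationGrid, TensorGridFitter,
                               build_grid, fit_curve, monte_carlo_errors,
                               order_parameter)


class TestBuildGrid:
    def test_grid_point_enumeration_matches_published_count(self, powder_small):
        # 1030-15,000 Hz step 30 and eta 0-1 step 0.05 give 466 x 21 = 9786
        # simulations; verified here on the axes of a cheap 2-point build
        timing = PulseTiming.shifted(n_rotor_periods_list=(2, 4))
        grid = build_grid(timing, powder=PowderScheme(3, 2), **PAPER_GRID)
        assert len(grid.anisotropy_values) == 466
        assert len(grid.asymmetry_values) == 21
        assert grid.n_curves == 9786

    def test_degenerate_single_anisotropy_grid(self, timing_small):
        grid = build_grid(timing_small, 100.0, 100.0, 30.0, 1.0,
                          PowderScheme(3, 2))
        assert grid.n_curves == 2  # 1 anisotropy x eta in {0, 1}

    def test_small_enumerated_grid(self, timing_small):
        grid = build_grid(timing_small, 100.0, 160.0, 30.0, 0.5,
                          PowderScheme(3, 2))
        assert list(grid.anisotropy_values) == [100.0, 130.0, 160.0]
        assert list(grid.asymmetry_values) == [0.0, 0.5, 1.0]
        assert grid.n_curves == 9

    def test_invalid_parameters_rejected(self, timing_small):
        with pytest.raises(ValueError):
            build_grid(timing_small, -5.0, 100.0, 30.0, 0.5)
        with pytest.raises(ValueError):
            build_grid(timing_small, 100.0, 200.0, 0.0, 0.5)

    def test_grid_matches_direct_simulation(self, small_grid, timing_small,
                                            powder_small):
        direct = simulate_redor(DipolarTensor(5500.0, 0.5), timing_small,
                                powder_small)
        assert np.allclose(small_grid.curve(5500.0, 0.5).dephasing,
                           direct.dephasing, atol=1e-10)

    def test_cache_roundtrip(self, timing_small, tmp_path):
        kw = dict(aniso_min=4500.0, aniso_max=4800.0, aniso_step=150.0,
                  eta_step=0.5, powder=PowderScheme(5, 2))
        g1 = build_grid(timing_small, cache_dir=tmp_path, **kw)
        g2 = build_grid(timing_small, cache_dir=tmp_path, **kw)
        assert np.allclose(g1.dephasing, g2.dephasing)
        assert g2.timing.mas_frequency == timing_small.mas_frequency


class TestFitCurve:
    def test_noiseless_grid_member_recovered_exactly(self, small_grid):
        obs = small_grid.curve(5050.0, 0.25)
        obs.noise_sigma = 0.02
        res = fit_curve(obs, small_grid)
        assert res.best_tensor.anisotropy == 5050.0
        assert res.best_tensor.asymmetry == 0.25
        assert res.chi_square == 0.0

    def test_all_zero_observation_picks_flattest_curve(self, small_grid):
        obs = RedorCurve(small_grid.dephasing_times,
                         np.zeros_like(small_grid.dephasing_times), 0.05)
        res = fit_curve(obs, small_grid)
        assert res.best_tensor.anisotropy == small_grid.anisotropy_values[0]

    def test_time_grid_mismatch_raises_without_interpolation(self, small_grid):
        obs = RedorCurve(small_grid.dephasing_times[:-1] * 1.01,
                         small_grid.dephasing[0, 0, :-1], 0.05)
        with pytest.raises(ValueError, match="dephasing times"):
            fit_curve(obs, small_grid)
        fit_curve(obs, small_grid, interpolate=True)  # no raise

    def test_seeded_noise_recovery_within_one_grid_step(self, small_grid):
        truth = (5500.0, 0.5)
        clean = small_grid.curve(*truth)
        sigma = 0.03
        hits = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            obs = RedorCurve(clean.dephasing_times,
                             clean.dephasing + rng.normal(0, sigma,
                                                          clean.dephasing.size),
                             sigma)
            hits.append(fit_curve(obs, small_grid).best_tensor.anisotropy)
        values, counts = np.unique(hits, return_counts=True)
        modal = values[np.argmax(counts)]
        step = small_grid.anisotropy_values[1] - small_grid.anisotropy_values[0]
        assert abs(modal - truth[0]) <= step

    def test_chi_square_uses_noise_weighting(self, small_grid):
        obs = small_grid.curve(5500.0, 0.0)
        obs.dephasing = obs.dephasing + 0.01
        obs.noise_sigma = 0.1
        loose = fit_curve(obs, small_grid).chi_square
        obs.noise_sigma = 0.01
        tight = fit_curve(obs, small_grid).chi_square
        assert tight == pytest.approx(loose * 100.0, rel=1e-9)


class TestMonteCarloErrors:
    def test_zero_noise_gives_zero_sds(self, small_grid):
        res = fit_curve(small_grid.curve(5500.0, 0.25), small_grid)
        res = monte_carlo_errors(res, small_grid, 0.0, 50, seed=1)
        assert res.anisotropy_sd == res.asymmetry_sd == res.s_squared_sd == 0.0

    def test_same_seed_reproduces_sds(self, small_grid):
        res = fit_curve(small_grid.curve(5500.0, 0.25), small_grid)
        a = monte_carlo_errors(res, small_grid, 0.05, 200, seed=11)
        b = monte_carlo_errors(res, small_grid, 0.05, 200, seed=11)
        assert a.anisotropy_sd == b.anisotropy_sd
        assert a.s_squared_sd == b.s_squared_sd

    def test_sd_shrinks_with_noise(self, small_grid):
        res = fit_curve(small_grid.curve(5500.0, 0.25), small_grid)
        sds = [monte_carlo_errors(res, small_grid, sig, 400, seed=5).anisotropy_sd
               for sig in (0.08, 0.04, 0.02)]
        assert sds[0] > sds[1] > sds[2]

    def test_truncation_bounds_noise(self, small_grid):
        # truncated draws at +-3 sigma never move a point further than that
        rng_state = 17
        base = small_grid.curve(5500.0, 0.25).dephasing
        noise = truncnorm.rvs(-3, 3, scale=0.05, size=(500, base.size),
                              random_state=np.random.default_rng(rng_state))
        assert np.max(np.abs(noise)) <= 0.15 + 1e-12

    def test_replicate_count_validated(self, small_grid):
        res = fit_curve(small_grid.curve(5500.0, 0.25), small_grid)
        with pytest.raises(ValueError):
            monte_carlo_errors(res, small_grid, 0.05, 1, seed=0)


class TestOrderParameter:
    def test_rigid_limit_maps_to_one(self):
        assert order_parameter(methyl_rigid_limit()) == pytest.approx(1.0)

    def test_half_coupling_gives_quarter(self):
        assert order_parameter(methyl_rigid_limit() / 2) == pytest.approx(0.25)

    def test_published_flexible_site_value(self):
        # sqrt(0.15) x rigid limit back-translates to S^2 = 0.150
        assert order_parameter(np.sqrt(0.15) * methyl_rigid_limit()) \
            == pytest.approx(0.150, abs=1e-9)
        assert order_parameter(5627.0, 14529.0) == pytest.approx(0.150, abs=5e-4)

    def test_above_rigid_limit_rejected(self):
        with pytest.raises(ValueError):
            order_parameter(15000.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_strictly_increasing(self, f1, f2):
        lo, hi = sorted((f1, f2))
        rigid = methyl_rigid_limit()
        if hi > lo:
            assert order_parameter(hi * rigid) > order_parameter(lo * rigid) \
                or lo == hi


class TestTensorGridFitter:
    def test_sklearn_style_fit_and_attributes(self, small_grid):
        obs = small_grid.curve(5950.0, 0.75)
        est = TensorGridFitter(small_grid, noise_sigma=0.05, n_mc=100, seed=2)
        est.fit(obs.dephasing_times, obs.dephasing)
        assert est.anisotropy_ == 5950.0
        assert est.asymmetry_ == 0.75
        assert est.chi_square_ == 0.0
        assert est.s_squared_ == pytest.approx(
            (5950.0 / methyl_rigid_limit()) ** 2)
        assert est.s_squared_sd_ > 0
        pred = est.predict(obs.dephasing_times)
        assert np.allclose(pred, obs.dephasing, atol=1e-10)

    def test_get_params_roundtrip(self, small_grid):
        est = TensorGridFitter(small_grid, noise_sigma=0.03, n_mc=10, seed=7)
        params = est.get_params()
        assert params["noise_sigma"] == 0.03
        est.set_params(noise_sigma=0.06)
        assert est.noise_sigma == 0.06
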