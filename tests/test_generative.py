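"""Forward model: integrator accuracy, Stratonovich convention, observers,
reduced models and the noise decomposition."""

import numpy as np
import pytest
from scipy import stats

from sysobs.generative import (
    GenerativeParams,
    NoiseSpec,
    SimulationDivergenceError,
    make_reduced_params,
    observe,
    simulate_latent,
    stratonovich_difference,
)
from sysobs.stimulus import DriverSignal


def _driver(duration=4.0, fs=250.0, value=0.0):
    n = int(round(duration * fs))
    times = np.arange(n) / fs
    return DriverSignal(times=times, values=np.full(n, value),
                        scene_boundaries=np.empty(0))


class TestSimulateLatent:
    def test_zero_fixed_point(self, quiet):
        params = GenerativeParams(a=-1.0, b=0.0)
        latent = simulate_latent(params, _driver(), quiet, dt=0.004)
        assert np.all(latent.x_mu == 0.0)
        assert np.all(latent.x_M == 0.0)

    def test_linear_ode_closed_form(self, quiet):
        # x' = -x from x(0)=1 has x(t) = exp(-t); Heun global error O(dt^2)
        params = GenerativeParams(a=-1.0, b=0.0)
        dt = 0.004
        latent = simulate_latent(params, _driver(duration=1.0), quiet, dt=dt,
                                 x0=(1.0, 1.0))
        err = abs(latent.x_mu[-1] - np.exp(-latent.times[-1]))
        assert err < 10 * dt**2

    def test_heun_is_second_order(self, quiet):
        # halving dt should reduce the endpoint error about fourfold
        params = GenerativeParams(a=-1.0, b=0.0)
        errs = []
        for dt in (0.008, 0.004):
            latent = simulate_latent(params, _driver(duration=1.0), quiet, dt=dt,
                                     x0=(1.0, 1.0))
            errs.append(abs(latent.x_mu[-1] - np.exp(-latent.times[-1])))
        order = np.log2(errs[0] / errs[1])
        assert 1.7 <= order <= 2.3

    def test_seed_determinism_bit_level(self, default_params, scene_driver):
        noise = NoiseSpec(mode="additive", seed=42)
        a = simulate_latent(default_params, scene_driver, noise, dt=0.004)
        b = simulate_latent(default_params, scene_driver, noise, dt=0.004)
        assert a.x_mu.tobytes() == b.x_mu.tobytes()
        assert a.x_M.tobytes() == b.x_M.tobytes()
        assert a.noise_path_mu.tobytes() == b.noise_path_mu.tobytes()

    def test_invalid_dt_rejected(self, default_params, scene_driver, quiet):
        with pytest.raises(ValueError, match="dt"):
            simulate_latent(default_params, scene_driver, quiet, dt=0.0)

    def test_divergence_reported_with_step(self, quiet):
        with pytest.warns(UserWarning, match="non-negative"):
            params = GenerativeParams(a=5.0, b=1.0)
        with pytest.raises(SimulationDivergenceError, match="step"):
            simulate_latent(params, _driver(value=1.0), quiet, dt=0.004,
                            x0=(1.0, 1.0))

    def test_mode_none_forces_zero_noise(self, default_params, scene_driver):
        latent = simulate_latent(default_params, scene_driver,
                                 NoiseSpec(mode="none", seed=3), dt=0.004)
        assert latent.noise_path_mu.size == 0

    def test_shared_noise_identical_params_gives_identical_channels(
        self, scene_driver
    ):
        # delta_a = delta_k = 0 with one Wiener path: the two scales coincide
        params = GenerativeParams(sigma_mu=0.2, sigma_M=0.2, obs_noise_sd=0.0)
        noise = NoiseSpec(mode="additive", shared_increments=True, seed=5)
        latent = simulate_latent(params, scene_driver, noise, dt=0.004)
        np.testing.assert_array_equal(latent.x_mu, latent.x_M)
        pair = observe(latent, params, seed=0)
        np.testing.assert_array_equal(pair.h_mu, pair.h_M)

    def test_independent_increments_differ(self, scene_driver):
        params = GenerativeParams(sigma_mu=0.2, sigma_M=0.2)
        noise = NoiseSpec(mode="additive", shared_increments=False, seed=5)
        latent = simulate_latent(params, scene_driver, noise, dt=0.004)
        assert not np.array_equal(latent.x_mu, latent.x_M)


@pytest.fixture(scope="module")
def log_endpoints():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # a=0 is marginal by design
        params = GenerativeParams(a=0.0, b=0.0, sigma_mu=0.5, sigma_M=0.5)
    driver = _driver(duration=1.0)
    out = np.empty(2000)
    for s in range(2000):
        latent = simulate_latent(
            params, driver, NoiseSpec(mode="multiplicative", seed=s),
            dt=0.004, x0=(1.0, 1.0),
        )
        out[s] = np.log(latent.x_mu[-1])
    return out


class TestStratonovichConvention:
    """dx = sigma x o dW must have the ordinary-calculus solution
    x(t) = x(0) exp(sigma W(t)), i.e. log-state ~ N(ln x0, sigma^2 t)."""

    def test_log_state_moments(self, log_endpoints):
        n = len(log_endpoints)
        # exact solution: ln x(1) ~ N(0, 0.25)
        se_mean = 0.5 / np.sqrt(n)
        assert abs(log_endpoints.mean()) < 3 * se_mean
        var = log_endpoints.var(ddof=1)
        se_var = 0.25 * np.sqrt(2.0 / (n - 1))
        assert abs(var - 0.25) < 3 * se_var

    def test_log_state_is_gaussian(self, log_endpoints):
        stat, p = stats.kstest(log_endpoints, "norm", args=(0.0, 0.5))
        assert p > 0.01


class TestObserve:
    def test_zero_state_maps_to_zero(self, flat_driver, quiet):
        params = GenerativeParams(a=-1.0, b=0.0, c=2.0, k=0.5)
        latent = simulate_latent(params, flat_driver, quiet, dt=0.004)
        pair = observe(latent, params, seed=0)
        assert np.all(pair.h_mu == 0.0)
        assert np.all(pair.h_M == 0.0)

    def test_saturation_bound(self, scene_driver, quiet):
        # tanh observers keep |h| < c in the noise-free case
        params = GenerativeParams(a=-0.5, b=2.0, c=1.5, k=2.0, delta_k=1.0)
        latent = simulate_latent(params, scene_driver, quiet, dt=0.004)
        pair = observe(latent, params, seed=0)
        assert np.all(np.abs(pair.h_mu) < params.c)
        assert np.all(np.abs(pair.h_M) < params.c)

    def test_small_signal_linearisation(self):
        params = GenerativeParams(c=2.0, k=0.5)
        times = np.arange(4) * 0.004
        from sysobs.generative import LatentTrajectory

        x = np.full(4, 0.01)
        latent = LatentTrajectory(
            times=times, x_mu=x, x_M=x, noise_path_mu=np.empty(0),
            noise_path_M=np.empty(0), driver_values=np.zeros(4),
        )
        pair = observe(latent, params, seed=0)
        expected = params.c * params.k * 0.01
        assert np.allclose(pair.h_mu, expected, rtol=1e-4)

    def test_observation_noise_streams_independent(self, scene_driver, quiet):
        params = GenerativeParams(obs_noise_sd=0.1)
        latent = simulate_latent(params, scene_driver, quiet, dt=0.004)
        pair = observe(latent, params, seed=9)
        clean = observe(latent, params.replace(obs_noise_sd=0.0), seed=9)
        e_mu = pair.h_mu - clean.h_mu
        e_M = pair.h_M - clean.h_M
        assert abs(np.corrcoef(e_mu, e_M)[0, 1]) < 0.15


class TestReducedModels:
    @pytest.mark.parametrize(
        "which,expect",
        [
            ("identical_observers", {"delta_a": 0.5, "delta_k": 0.0}),
            ("identical_systems", {"delta_a": 0.0, "delta_k": 0.3}),
        ],
    )
    def test_pins_the_right_deviation(self, which, expect):
        full = GenerativeParams(delta_a=0.5, delta_k=0.3)
        red = make_reduced_params(full, which)
        assert red.delta_a == expect["delta_a"]
        assert red.delta_k == expect["delta_k"]

    def test_already_reduced_is_unchanged(self):
        full = GenerativeParams(delta_a=0.0, delta_k=0.0)
        for which in ("identical_observers", "identical_systems"):
            assert make_reduced_params(full, which) == full

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError, match="unknown reduced model"):
            make_reduced_params(GenerativeParams(), "identical_everything")


class TestStratonovichDifference:
    def test_identical_models_cancel_exactly(self, scene_driver):
        params = GenerativeParams(sigma_mu=0.2, sigma_M=0.2)
        noise = NoiseSpec(mode="additive", shared_increments=True, seed=7)
        latent = simulate_latent(params, scene_driver, noise, dt=0.004)
        deg, obs_only = stratonovich_difference(params, latent)
        assert np.allclose(deg, 0.0, atol=1e-14)
        assert np.allclose(obs_only, 0.0, atol=1e-14)

    def test_equal_initial_states(self, scene_driver):
        # at t=0 both states are 0, so the degenerate term vanishes and the
        # observer-only term is (sigma_mu - sigma_M) * xi(0) * c * k
        params = GenerativeParams(sigma_mu=0.3, sigma_M=0.1, b=0.0)
        noise = NoiseSpec(mode="additive", shared_increments=True, seed=7)
        latent = simulate_latent(params, scene_driver, noise, dt=0.004)
        deg, obs_only = stratonovich_difference(params, latent)
        assert deg[0] == pytest.approx(0.0, abs=1e-14)
        xi0 = latent.noise_path_mu[0] / latent.dt
        expected = (0.3 - 0.1) * xi0 * params.c * params.k
        assert obs_only[0] == pytest.approx(expected, rel=1e-12)

    def test_decomposition_matches_finite_difference(self, scene_driver):
        # oracle: forward finite differences of the noise-free observation
        params = GenerativeParams(delta_a=0.5, delta_k=0.3, sigma_mu=0.2,
                                  sigma_M=0.2)
        noise = NoiseSpec(mode="additive", shared_increments=True, seed=13)
        dt = 0.004
        latent = simulate_latent(params, scene_driver, noise, dt=dt)
        pair = observe(latent, params.replace(obs_noise_sd=0.0), seed=0)
        diff = pair.h_mu - pair.h_M
        fd = np.diff(diff) / dt
        deg, obs_only = stratonovich_difference(params, latent)
        resid = fd - (deg + obs_only)
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert rms(resid) <= 10 * dt * rms(fd)

    def test_noise_free_observer_term_is_zero(self, scene_driver, quiet):
        params = GenerativeParams(delta_a=0.5)
        latent = simulate_latent(params, scene_driver, quiet, dt=0.004)
        deg, obs_only = stratonovich_difference(params, latent)
        assert np.all(obs_only == 0.0)
        assert np.any(deg != 0.0)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"c": 0.0}, {"k": -1.0}, {"k": 0.5, "delta_k": -0.5},
                   {"sigma_mu": -0.1}, {"obs_noise_sd": -1.0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenerativeParams(**kwargs)

    def test_unstable_rate_warns(self):
        with pytest.warns(UserWarning, match="diverge"):
            GenerativeParams(a=0.5)
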