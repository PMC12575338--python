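"""Forward generative models for cross-scale neural recordings.

Two latent states — a microscopic one ``x_mu`` and a macroscopic one
``x_M`` — evolve under linear time-invariant dynamics driven by a shared
exogenous input, optionally perturbed by additive or multiplicative
(state-dependent) Stratonovich noise:

    dx_mu = (a x_mu + b v) dt            + sigma_mu  [x_mu] o dW
    dx_M  = ((a + da) x_M + b v) dt      + sigma_M   [x_M]  o dW

Each scale is read out through a saturating observer function

    h = c * tanh(k_eff * x) + obs_noise,   k_eff = k (micro), k + dk (macro)

so that a difference between the two recorded channels can originate in
the dynamics (``delta_a``), in the observation mapping (``delta_k``), or
in both.  The multiplicative bracket applies only in the
``multiplicative`` noise mode.  All integration uses the Heun
predictor–corrector scheme, which converges to the Stratonovich solution
without an explicit drift correction.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .stimulus import DriverSignal

__all__ = [
    "GenerativeParams",
    "NoiseSpec",
    "LatentTrajectory",
    "ObservedPair",
    "SimulationDivergenceError",
    "simulate_latent",
    "observe",
    "make_reduced_params",
    "stratonovich_difference",
    "trajectory_to_frame",
]

NOISE_MODES = ("none", "additive", "multiplicative")

#: states larger than this abort the integration with a diagnostic
DIVERGENCE_LIMIT = 1e6


class SimulationDivergenceError(RuntimeError):
    """Raised when the latent state blows up during integration."""

    def __init__(self, step: int, value: float):
        self.step = step
        self.value = value
        super().__init__(
            f"latent state diverged (|x| = {value:.3g} > {DIVERGENCE_LIMIT:.0e}) "
            f"at step {step}"
        )


@dataclass(frozen=True)
class GenerativeParams:
    """Scalar parameters of the two-scale generative model.

    Parameters
    ----------
    a : float
        Intrinsic rate of the microscopic dynamics (1/s); negative for
        stability.
    b : float
        Input gain shared by both scales (dimensionless).
    delta_a : float
        Deviation of the macroscopic rate from ``a`` (1/s).
    c : float
        Observer amplitude — the saturation level of the tanh readout
        (signal units).
    k : float
        Observer input gain of the microscopic channel (1/state-units).
    delta_k : float
        Deviation of the macroscopic observer gain from ``k``.
    sigma_mu, sigma_M : float
        Volatility constants of the process noise (state-units/sqrt(s)).
    obs_noise_sd : float
        Standard deviation of additive white observation noise
        (signal units).
    """

    a: float = -1.0
    b: float = 1.0
    delta_a: float = 0.0
    c: float = 1.0
    k: float = 1.0
    delta_k: float = 0.0
    sigma_mu: float = 0.0
    sigma_M: float = 0.0
    obs_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"observer amplitude c must be positive, got {self.c}")
        if self.k <= 0:
            raise ValueError(f"observer gain k must be positive, got {self.k}")
        if self.k + self.delta_k <= 0:
            raise ValueError(
                f"macro observer gain k + delta_k must be positive, "
                f"got {self.k + self.delta_k}"
            )
        for name in ("sigma_mu", "sigma_M", "obs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.a >= 0 or self.a + self.delta_a >= 0:
            warnings.warn(
                "non-negative dynamic rate (a or a + delta_a); the latent "
                "state may diverge",
                stacklevel=2,
            )

    def replace(self, **changes) -> "GenerativeParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class NoiseSpec:
    """Process-noise configuration of a simulation.

    ``shared_increments`` selects whether one Wiener path drives both
    scales (the default) or each scale receives an independent path.
    ``mode='none'`` forces zero process noise regardless of the sigma
    values stored in :class:`GenerativeParams`.
    """

    mode: str = "none"
    shared_increments: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in NOISE_MODES:
            raise ValueError(f"noise mode must be one of {NOISE_MODES}, got {self.mode!r}")


@dataclass
class LatentTrajectory:
    """Latent paths of both scales plus the realized noise increments."""

    times: np.ndarray
    x_mu: np.ndarray
    x_M: np.ndarray
    noise_path_mu: np.ndarray  # Wiener increments, length n-1 (empty if noise-free)
    noise_path_M: np.ndarray
    driver_values: np.ndarray  # driver interpolated onto the simulation grid
    noise_mode: str = "none"

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("x_mu", "x_M", "driver_values"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match times")
        dt = np.diff(self.times)
        if n > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9)):
            raise ValueError("times must be strictly increasing with constant step")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ObservedPair:
    """The two observed channels on a shared time grid."""

    times: np.ndarray
    h_mu: np.ndarray
    h_M: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        n = len(self.times)
        if len(self.h_mu) != n or len(self.h_M) != n:
            raise ValueError("channel lengths do not match times")
        if not (np.all(np.isfinite(self.h_mu)) and np.all(np.isfinite(self.h_M))):
            raise ValueError("observed channels contain non-finite values")


def _drift_rates(params: GenerativeParams) -> tuple[float, float]:
    return params.a, params.a + params.delta_a


def _wiener_increments(
    noise: NoiseSpec, params: GenerativeParams, n_steps: int, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the per-step Wiener increments for both scales.

    Uses a counter-based (Philox) stream keyed by the noise seed so that
    identical seeds give bit-identical paths.
    """
    if noise.mode == "none" or (params.sigma_mu == 0 and params.sigma_M == 0):
        empty = np.empty(0)
        return empty, empty
    rng = np.random.Generator(np.random.Philox(key=noise.seed))
    dw_mu = rng.normal(0.0, np.sqrt(dt), size=n_steps)
    if noise.shared_increments:
        dw_M = dw_mu
    else:
        dw_M = rng.normal(0.0, np.sqrt(dt), size=n_steps)
    return dw_mu, dw_M


def _heun_linear(
    alpha: float, b: float, v: np.ndarray, dt: float, sigma_dw: np.ndarray | None,
    x0: float,
) -> np.ndarray:
    """Heun integration of dx = (alpha x + b v) dt + sigma dW (additive noise).

    For constant-coefficient drift the Heun update is the linear
    recurrence  x[n+1] = phi x[n] + u[n]  with

        phi  = 1 + alpha dt + (alpha dt)^2 / 2
        u[n] = (b dt / 2) ((1 + alpha dt) v[n] + v[n+1])
               + sigma dW[n] (1 + alpha dt / 2)

    which is evaluated with a direct IIR filter.
    """
    ad = alpha * dt
    phi = 1.0 + ad + 0.5 * ad * ad
    u = 0.5 * b * dt * ((1.0 + ad) * v[:-1] + v[1:])
    if sigma_dw is not None:
        u = u + sigma_dw * (1.0 + 0.5 * ad)
    y, _ = lfilter([1.0], [1.0, -phi], u, zi=np.array([phi * x0]))
    return np.concatenate(([x0], y))


def _heun_multiplicative(
    alpha: float, b: float, v: np.ndarray, dt: float, sigma: float,
    dw: np.ndarray, x0: float,
) -> np.ndarray:
    """Heun integration of dx = (alpha x + b v) dt + sigma x o dW."""
    n = len(v)
    x = np.empty(n)
    x[0] = x0
    xc = x0
    for i in range(n - 1):
        dwi = dw[i] if sigma > 0 else 0.0
        drift0 = alpha * xc + b * v[i]
        xp = xc + dt * drift0 + sigma * xc * dwi
        drift1 = alpha * xp + b * v[i + 1]
        xc = xc + 0.5 * dt * (drift0 + drift1) + 0.5 * sigma * (xc + xp) * dwi
        x[i + 1] = xc
    return x


def simulate_latent(
    params: GenerativeParams,
    driver: DriverSignal,
    noise: NoiseSpec,
    dt: float,
    *,
    x0: tuple[float, float] = (0.0, 0.0),
) -> LatentTrajectory:
    """Integrate the two-scale latent dynamics with the Heun scheme.

    The driver is linearly interpolated onto the simulation grid, which
    spans the driver's support with step ``dt``.  Initial conditions are
    zero by default; ``x0`` exists for testing closed-form solutions.

    Raises
    ------
    SimulationDivergenceError
        If either latent path exceeds :data:`DIVERGENCE_LIMIT`.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    t0, t1 = float(driver.times[0]), float(driver.times[-1])
    n = int(round((t1 - t0) / dt)) + 1
    times = t0 + dt * np.arange(n)
    v = np.interp(times, driver.times, driver.values)

    alpha_mu, alpha_M = _drift_rates(params)
    dw_mu, dw_M = _wiener_increments(noise, params, n - 1, dt)
    have_noise = dw_mu.size > 0

    if noise.mode == "multiplicative" and have_noise:
        x_mu = _heun_multiplicative(alpha_mu, params.b, v, dt, params.sigma_mu, dw_mu, x0[0])
        x_M = _heun_multiplicative(alpha_M, params.b, v, dt, params.sigma_M, dw_M, x0[1])
    else:
        s_mu = params.sigma_mu * dw_mu if have_noise else None
        s_M = params.sigma_M * dw_M if have_noise else None
        x_mu = _heun_linear(alpha_mu, params.b, v, dt, s_mu, x0[0])
        x_M = _heun_linear(alpha_M, params.b, v, dt, s_M, x0[1])

    for x in (x_mu, x_M):
        bad = ~np.isfinite(x) | (np.abs(x) > DIVERGENCE_LIMIT)
        if np.any(bad):
            step = int(np.argmax(bad))
            raise SimulationDivergenceError(step, float(np.abs(x[step])))

    return LatentTrajectory(
        times=times,
        x_mu=x_mu,
        x_M=x_M,
        noise_path_mu=dw_mu,
        noise_path_M=dw_M,
        driver_values=v,
        noise_mode=noise.mode if have_noise else "none",
    )


def observer_gains(params: GenerativeParams) -> tuple[float, float]:
    """Effective observer input gains (micro, macro)."""
    return params.k, params.k + params.delta_k


def observe(
    latent: LatentTrajectory, params: GenerativeParams, seed: int = 0
) -> ObservedPair:
    """Map latent states through the tanh observers, adding measurement noise.

    ``h_mu = c tanh(k x_mu) + eps`` and ``h_M = c tanh((k + dk) x_M) + eps'``
    with independent white Gaussian noise of SD ``obs_noise_sd`` per channel.
    """
    k_mu, k_M = observer_gains(params)
    h_mu = params.c * np.tanh(k_mu * latent.x_mu)
    h_M = params.c * np.tanh(k_M * latent.x_M)
    if params.obs_noise_sd > 0:
        rng = np.random.Generator(np.random.Philox(key=seed))
        h_mu = h_mu + rng.normal(0.0, params.obs_noise_sd, size=h_mu.shape)
        h_M = h_M + rng.normal(0.0, params.obs_noise_sd, size=h_M.shape)
    return ObservedPair(
        times=latent.times.copy(), h_mu=h_mu, h_M=h_M, fs=1.0 / latent.dt
    )


REDUCED_MODELS = ("identical_observers", "identical_systems")


def make_reduced_params(full: GenerativeParams, which: str) -> GenerativeParams:
    """Construct a reduced model from the full parameter set.

    ``identical_observers`` pins ``delta_k = 0`` so all cross-scale
    difference lives in the dynamics; ``identical_systems`` pins
    ``delta_a = 0`` so it lives in the observation mappings.
    """
    if which == "identical_observers":
        return full.replace(delta_k=0.0)
    if which == "identical_systems":
        return full.replace(delta_a=0.0)
    raise ValueError(f"unknown reduced model {which!r}; expected one of {REDUCED_MODELS}")


def _observer_derivative(params: GenerativeParams, x: np.ndarray, gain: float) -> np.ndarray:
    # d/dx [c tanh(g x)] = c g sech^2(g x)
    t = np.tanh(gain * x)
    return params.c * gain * (1.0 - t * t)


def stratonovich_difference(
    params: GenerativeParams, latent: LatentTrajectory
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose d/dt (h_mu - h_M) into degenerate and observer-only parts.

    Along the stored path, the rate of change of the observed difference
    splits into

        degenerate(t)    = g_mu'(x_mu) f_mu - g_M'(x_M) f_M
        observer_only(t) = amp_mu xi_mu g_mu'(x_mu) - amp_M xi_M g_M'(x_M)

    where ``xi`` is the stored Wiener increment divided by ``dt`` and
    ``amp`` is the noise amplitude (``sigma`` for additive noise,
    ``sigma x`` for multiplicative).  The degenerate part conflates
    system and observer properties; the observer-only part depends on
    the observer sensitivities alone, which is what makes noisy data
    informative about the observation mappings.  Both series are
    evaluated at the left endpoint of each integration step (length
    ``n - 1``).
    """
    x_mu = latent.x_mu[:-1]
    x_M = latent.x_M[:-1]
    v = latent.driver_values[:-1]
    dt = latent.dt
    alpha_mu, alpha_M = _drift_rates(params)
    k_mu, k_M = observer_gains(params)

    gp_mu = _observer_derivative(params, x_mu, k_mu)
    gp_M = _observer_derivative(params, x_M, k_M)
    f_mu = alpha_mu * x_mu + params.b * v
    f_M = alpha_M * x_M + params.b * v
    degenerate = gp_mu * f_mu - gp_M * f_M

    if latent.noise_path_mu.size == 0:
        observer_only = np.zeros_like(degenerate)
        return degenerate, observer_only

    if latent.noise_path_mu.size != len(x_mu):
        raise ValueError(
            "stored noise increments do not match the trajectory length"
        )
    xi_mu = latent.noise_path_mu / dt
    xi_M = latent.noise_path_M / dt
    if latent.noise_mode == "multiplicative":
        amp_mu = params.sigma_mu * x_mu
        amp_M = params.sigma_M * x_M
    else:
        amp_mu = params.sigma_mu
        amp_M = params.sigma_M
    observer_only = amp_mu * xi_mu * gp_mu - amp_M * xi_M * gp_M
    return degenerate, observer_only


def trajectory_to_frame(latent: LatentTrajectory, observed: ObservedPair):
    """Tidy table of a simulation: time, x_mu, x_M, h_mu, h_M, driver."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time": latent.times,
            "x_mu": latent.x_mu,
            "x_M": latent.x_M,
            "h_mu": observed.h_mu,
            "h_M": observed.h_M,
            "driver": latent.driver_values,
        }
    )
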