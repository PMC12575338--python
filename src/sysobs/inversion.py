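"""Variational-Laplace model inversion.

The full generative model is fit to an observed channel pair by Gaussian
fixed-form variational inference over a small set of free parameters
(by default the macroscopic deviations ``delta_a`` and ``delta_k``, plus
one shared log observation precision).  The variational free energy

    F = <log p(y | theta)>_q  -  KL[q(theta) || p(theta)]

is maximised over the mean of ``q`` by damped Gauss–Newton ascent, with
the posterior covariance taken as the inverse negative curvature at the
optimum.  Under the Laplace assumption this F equals

    F = log p(y | m) + log p(m) + 1/2 log|2 pi Sigma|

which is exact for linear-Gaussian models and therefore testable
against closed-form evidence.

The likelihood is a prediction-error density: for deterministic models,
independent Gaussian residuals around the noise-free forward
prediction; for stochastic models, the innovation decomposition of a
continuous-discrete extended Kalman filter whose mean follows the Heun
integrator and whose covariance follows the linearised dynamics with
process-noise intensity ``sigma^2`` (scaled by the squared state for
multiplicative noise).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .generative import (
    GenerativeParams,
    NoiseSpec,
    ObservedPair,
    observe,
    observer_gains,
    simulate_latent,
)
from .stimulus import DriverSignal

__all__ = [
    "GaussianBelief",
    "InversionSettings",
    "default_prior",
    "predict",
    "loglik",
    "laplace_fit",
    "variational_laplace",
]

log = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)

#: generative fields that free parameters may override
_GENERATIVE_FIELDS = frozenset(
    {"a", "b", "delta_a", "c", "k", "delta_k", "sigma_mu", "sigma_M", "obs_noise_sd"}
)

#: label of the optional shared log observation-precision hyperparameter
LOG_PRECISION = "log_obs_precision"


@dataclass
class GaussianBelief:
    """Gaussian belief (prior or posterior) over named scalar parameters."""

    names: tuple
    mean: np.ndarray
    cov: np.ndarray
    free_energy: float | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.cov = np.asarray(self.cov, dtype=float)
        d = len(self.names)
        if self.mean.shape != (d,) or self.cov.shape != (d, d):
            raise ValueError("names, mean and cov dimensions disagree")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric (within 1e-10)")
        if d and np.linalg.eigvalsh((self.cov + self.cov.T) / 2).min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"unknown parameter label {label!r}") from None

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.mean))

    def marginal_sd(self, label: str) -> float:
        i = self.index(label)
        return math.sqrt(max(self.cov[i, i], 0.0))

    def credible_interval(self, label: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        i = self.index(label)
        z = norm.ppf(0.5 + level / 2.0)
        sd = self.marginal_sd(label)
        return (self.mean[i] - z * sd, self.mean[i] + z * sd)

    def reorder(self, names) -> "GaussianBelief":
        """Return the same belief with parameters permuted into ``names``."""
        idx = [self.index(n) for n in names]
        return GaussianBelief(
            names=tuple(names),
            mean=self.mean[idx],
            cov=self.cov[np.ix_(idx, idx)],
            free_energy=self.free_energy,
            info=dict(self.info),
        )

    def logpdf(self, values: np.ndarray) -> float:
        """Gaussian log density at ``values`` (requires non-singular cov)."""
        d = len(self.names)
        r = np.asarray(values, dtype=float) - self.mean
        sign, logdet = np.linalg.slogdet(self.cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular covariance in logpdf")
        return float(-0.5 * (d * LOG2PI + logdet + r @ np.linalg.solve(self.cov, r)))

    def to_json_dict(self) -> dict:
        out = {
            "names": list(self.names),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "free_energy": self.free_energy,
        }
        if self.info:
            out["info"] = self.info
        return out


@dataclass(frozen=True)
class InversionSettings:
    """Optimiser configuration for :func:`laplace_fit`."""

    max_iterations: int = 64
    f_tolerance: float = 1e-3  # nats; on 3 consecutive accepted steps
    damping_init: float = 1.0
    estimate_obs_precision: bool = True
    log_precision_prior: tuple[float, float] = (2.0, 4.0)  # mean, variance
    fd_step: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.f_tolerance <= 0:
            raise ValueError("f_tolerance must be positive")


def default_prior(settings: InversionSettings | None = None) -> GaussianBelief:
    """Standard-normal prior over (delta_a, delta_k), plus the precision
    hyperprior when it is being estimated."""
    settings = settings or InversionSettings()
    names = ["delta_a", "delta_k"]
    mean = [0.0, 0.0]
    var = [1.0, 1.0]
    if settings.estimate_obs_precision:
        names.append(LOG_PRECISION)
        mean.append(settings.log_precision_prior[0])
        var.append(settings.log_precision_prior[1])
    return GaussianBelief(names=tuple(names), mean=np.array(mean), cov=np.diag(var))


def _apply_free_values(params: GenerativeParams, free_values: dict) -> GenerativeParams:
    changes = {k: v for k, v in free_values.items() if k in _GENERATIVE_FIELDS}
    unknown = set(free_values) - _GENERATIVE_FIELDS - {LOG_PRECISION}
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if not changes:
        return params
    with warnings.catch_warnings():
        # exploratory optimiser candidates may be transiently unstable;
        # divergence is caught and scored, not warned about
        warnings.simplefilter("ignore")
        return params.replace(**changes)


def predict(
    params: GenerativeParams,
    free_values: dict,
    driver: DriverSignal,
    noise: NoiseSpec,
) -> ObservedPair:
    """Deterministic mean prediction of both channels.

    Free values override the corresponding generative fields; the
    forward pass is always noise-free (process noise enters the
    likelihood through the filter, not the prediction).
    """
    p = _apply_free_values(params, {**free_values, "obs_noise_sd": 0.0})
    dt = 1.0 / driver.fs
    latent = simulate_latent(p, driver, NoiseSpec(mode="none"), dt)
    return observe(latent, p, seed=0)


def _gaussian_residual_loglik(
    observed: ObservedPair, pred: ObservedPair, precision: float
) -> float:
    r2 = float(np.sum((observed.h_mu - pred.h_mu) ** 2)
               + np.sum((observed.h_M - pred.h_M) ** 2))
    n = 2 * len(observed.times)
    return 0.5 * n * (math.log(precision) - LOG2PI) - 0.5 * precision * r2


def _ekf_loglik(
    observed: ObservedPair,
    params: GenerativeParams,
    driver: DriverSignal,
    noise: NoiseSpec,
    precision: float,
) -> float:
    """Innovation log-likelihood of a continuous-discrete EKF.

    State (x_mu, x_M); Heun mean propagation; Euler covariance
    propagation  P <- P + dt (A P + P A' + Q)  with
    Q = sigma sigma' (rank one when the Wiener path is shared);
    observation Jacobian c k_eff sech^2(k_eff x).  Covariance is kept
    symmetric positive-definite by clipping at 1e-12.
    """
    dt = 1.0 / observed.fs
    v = np.interp(observed.times, driver.times, driver.values)
    y1 = observed.h_mu
    y2 = observed.h_M
    n = len(y1)
    a1 = params.a
    a2 = params.a + params.delta_a
    b = params.b
    c = params.c
    k1, k2 = observer_gains(params)
    s1, s2 = params.sigma_mu, params.sigma_M
    mult = noise.mode == "multiplicative"
    shared = noise.shared_increments
    r = 1.0 / precision

    ll = 0.0
    x1 = 0.0
    x2 = 0.0
    p11 = p12 = p22 = 0.0
    repaired = False
    for i in range(n):
        if i > 0:
            # Heun mean step
            d1 = a1 * x1 + b * v[i - 1]
            d2 = a2 * x2 + b * v[i - 1]
            xp1 = x1 + dt * d1
            xp2 = x2 + dt * d2
            x1 = x1 + 0.5 * dt * (d1 + a1 * xp1 + b * v[i])
            x2 = x2 + 0.5 * dt * (d2 + a2 * xp2 + b * v[i])
            # Euler covariance step with process-noise intensity Q
            if mult:
                w1 = s1 * x1
                w2 = s2 * x2
            else:
                w1 = s1
                w2 = s2
            q11 = w1 * w1
            q22 = w2 * w2
            q12 = w1 * w2 if shared else 0.0
            p11 = p11 + dt * (2.0 * a1 * p11 + q11)
            p12 = p12 + dt * ((a1 + a2) * p12 + q12)
            p22 = p22 + dt * (2.0 * a2 * p22 + q22)
            if p11 < 1e-12:
                repaired = repaired or p11 < -1e-12
                p11 = 1e-12
            if p22 < 1e-12:
                repaired = repaired or p22 < -1e-12
                p22 = 1e-12
        # measurement update
        t1 = math.tanh(k1 * x1)
        t2 = math.tanh(k2 * x2)
        h1 = c * k1 * (1.0 - t1 * t1)
        h2 = c * k2 * (1.0 - t2 * t2)
        s11 = h1 * h1 * p11 + r
        s22 = h2 * h2 * p22 + r
        s12 = h1 * h2 * p12
        det = s11 * s22 - s12 * s12
        if det <= 0.0:  # innovation covariance lost definiteness; repair
            s12 = 0.0
            det = s11 * s22
            repaired = True
        n1 = y1[i] - c * t1
        n2 = y2[i] - c * t2
        quad = (s22 * n1 * n1 - 2.0 * s12 * n1 * n2 + s11 * n2 * n2) / det
        ll -= 0.5 * (2.0 * LOG2PI + math.log(det) + quad)
        # gain K = P H' S^-1   (H diagonal)
        ph11 = p11 * h1
        ph12 = p12 * h2
        ph21 = p12 * h1
        ph22 = p22 * h2
        k11 = (ph11 * s22 - ph12 * s12) / det
        k12 = (-ph11 * s12 + ph12 * s11) / det
        k21 = (ph21 * s22 - ph22 * s12) / det
        k22 = (-ph21 * s12 + ph22 * s11) / det
        x1 = x1 + k11 * n1 + k12 * n2
        x2 = x2 + k21 * n1 + k22 * n2
        # Joseph-free update (I - K H) P, then symmetrise and clip
        a11 = 1.0 - k11 * h1
        a12 = -k12 * h2
        a21 = -k21 * h1
        a22 = 1.0 - k22 * h2
        np11 = a11 * p11 + a12 * p12
        np12 = a11 * p12 + a12 * p22
        np21 = a21 * p11 + a22 * p12
        np22 = a21 * p12 + a22 * p22
        p11 = np11
        p12 = 0.5 * (np12 + np21)
        p22 = np22
        if p11 < 1e-12:
            repaired = repaired or p11 < -1e-12
            p11 = 1e-12
        if p22 < 1e-12:
            repaired = repaired or p22 < -1e-12
            p22 = 1e-12
        lim = math.sqrt(p11 * p22)
        if abs(p12) > lim:
            p12 = math.copysign(lim, p12)
        if not math.isfinite(x1) or not math.isfinite(x2):
            raise FloatingPointError(f"EKF state became non-finite at sample {i}")
    if repaired:
        log.info("EKF covariance lost definiteness; repaired by symmetric clipping")
    return ll


def loglik(
    free_values: dict,
    observed: ObservedPair,
    params: GenerativeParams,
    driver: DriverSignal,
    noise: NoiseSpec,
    obs_precision: float,
) -> float:
    """Prediction-error log likelihood of the observed pair (nats).

    Deterministic mode scores independent Gaussian residuals around the
    noise-free prediction; stochastic modes use the EKF innovation
    decomposition, which degenerates to the deterministic value when the
    volatilities are zero.
    """
    if obs_precision <= 0:
        raise ValueError(f"obs_precision must be positive, got {obs_precision}")
    p = _apply_free_values(params, free_values)
    stochastic = noise.mode != "none" and (p.sigma_mu > 0 or p.sigma_M > 0)
    if not stochastic:
        pred = predict(params, free_values, driver, noise)
        if len(pred.times) != len(observed.times):
            raise ValueError("observed and prediction grids are not aligned")
        return _gaussian_residual_loglik(observed, pred, obs_precision)
    return _ekf_loglik(observed, p, driver, noise, obs_precision)


# ---------------------------------------------------------------------------
# Laplace engine
# ---------------------------------------------------------------------------


def _grad_hess(fun, m: np.ndarray, step: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Central finite-difference value, gradient and Hessian of ``fun``."""
    d = len(m)
    f0 = fun(m)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = step
        fp[i] = fun(m + e)
        fm[i] = fun(m - e)
    grad = (fp - fm) / (2.0 * step)
    hess = np.empty((d, d))
    for i in range(d):
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / step**2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = step
            ej[j] = step
            fpp = fun(m + ei + ej)
            fpm = fun(m + ei - ej)
            fmp = fun(m - ei + ej)
            fmm = fun(m - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    return f0, grad, hess


def _posterior_cov(neg_hess: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Inverse of the negative curvature, repaired to positive-definite."""
    h = 0.5 * (neg_hess + neg_hess.T)
    w, vmat = np.linalg.eigh(h)
    w = np.maximum(w, floor)
    cov = (vmat / w) @ vmat.T
    return 0.5 * (cov + cov.T)


def _free_energy(j_val: float, neg_hess: np.ndarray) -> tuple[float, np.ndarray]:
    cov = _posterior_cov(neg_hess)
    sign, logdet = np.linalg.slogdet(2.0 * math.pi * cov)
    return j_val + 0.5 * logdet, cov


def laplace_fit(
    loglik_fn,
    prior: GaussianBelief,
    settings: InversionSettings | None = None,
) -> GaussianBelief:
    """Maximise the Laplace free energy of an arbitrary log likelihood.

    ``loglik_fn`` maps a parameter vector (ordered as ``prior.names``)
    to a log likelihood in nats.  Returns a Gaussian posterior whose
    ``free_energy`` approximates the log model evidence.  Ascent is
    Gauss–Newton with Levenberg–Marquardt diagonal damping: damping
    doubles on rejected steps and halves on accepted ones, and F never
    decreases across accepted iterations.
    """
    settings = settings or InversionSettings()
    d = len(prior.names)
    prior_prec = np.linalg.inv(prior.cov)

    def objective(m: np.ndarray) -> float:
        return float(loglik_fn(m)) + prior.logpdf(m)

    m = prior.mean.copy()
    j_val, grad, hess = _grad_hess(objective, m, settings.fd_step)
    f_val, cov = _free_energy(j_val, -hess)
    damping = settings.damping_init
    converged = False
    small_steps = 0
    n_iter = 0
    f_trace = [f_val]

    for n_iter in range(1, settings.max_iterations + 1):
        accepted = False
        for _ in range(9):  # up to 8 damping escalations, then give up
            diag = np.maximum(np.abs(np.diag(hess)), 1e-8)
            damped = -hess + damping * np.diag(diag)
            try:
                step = np.linalg.solve(damped, grad)
            except np.linalg.LinAlgError:
                damping *= 2.0
                continue
            if not np.all(np.isfinite(step)):
                damping *= 2.0
                continue
            cand = m + step
            try:
                j_c, grad_c, hess_c = _grad_hess(objective, cand, settings.fd_step)
                f_c, cov_c = _free_energy(j_c, -hess_c)
            except (FloatingPointError, np.linalg.LinAlgError, ValueError,
                    OverflowError, RuntimeError):
                damping *= 2.0
                continue
            if np.isfinite(f_c) and f_c >= f_val:
                delta_f = f_c - f_val
                m, j_val, grad, hess, f_val, cov = cand, j_c, grad_c, hess_c, f_c, cov_c
                damping = max(damping / 2.0, 1e-8)
                accepted = True
                f_trace.append(f_val)
                small_steps = small_steps + 1 if delta_f < settings.f_tolerance else 0
                break
            damping *= 2.0
        if not accepted:
            if damping > 1e12:
                raise np.linalg.LinAlgError(
                    "singular curvature: damping escalation failed 8 times"
                )
            # no uphill step exists at any tried damping: local optimum
            converged = True
            break
        if small_steps >= 3:
            converged = True
            break
    else:
        warnings.warn(
            f"variational Laplace did not converge in "
            f"{settings.max_iterations} iterations; returning best-so-far",
            stacklevel=2,
        )

    if small_steps >= 3 or not np.any(np.abs(grad) > 1e-3):
        converged = True
    return GaussianBelief(
        names=prior.names,
        mean=m,
        cov=cov,
        free_energy=f_val,
        info={
            "converged": bool(converged),
            "iterations": int(n_iter),
            "damping": float(damping),
            "f_trace": [float(x) for x in f_trace],
        },
    )


def variational_laplace(
    observed: ObservedPair,
    params: GenerativeParams,
    driver: DriverSignal,
    noise: NoiseSpec,
    prior: GaussianBelief | None = None,
    settings: InversionSettings | None = None,
) -> GaussianBelief:
    """Invert the full generative model on an observed pair.

    Free parameters are taken from the prior's labels; generative fields
    not listed there stay fixed at ``params``.  When the label
    ``log_obs_precision`` is present (the default), a shared log
    observation precision is estimated jointly with hyperprior
    N(2, 4); otherwise the precision is fixed at
    ``1 / obs_noise_sd**2``.
    """
    settings = settings or InversionSettings()
    if prior is None:
        prior = default_prior(settings)
    names = prior.names
    estimate_prec = LOG_PRECISION in names
    if not estimate_prec:
        if params.obs_noise_sd > 0:
            fixed_precision = 1.0 / params.obs_noise_sd**2
        else:
            fixed_precision = math.exp(settings.log_precision_prior[0])

    def loglik_fn(vec: np.ndarray) -> float:
        values = dict(zip(names, vec))
        if estimate_prec:
            lp = values.pop(LOG_PRECISION)
            if lp > 50.0 or lp < -50.0:
                raise OverflowError("log precision out of range")
            precision = math.exp(lp)
        else:
            precision = fixed_precision
        return loglik(values, observed, params, driver, noise, precision)

    return laplace_fit(loglik_fn, prior, settings)
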