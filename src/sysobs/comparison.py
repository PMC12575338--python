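"""Bayesian model reduction and model comparison.

After fitting the full model (free ``delta_a`` and ``delta_k``), each
reduced hypothesis is scored without refitting by changing the prior:
pinning a parameter — setting its prior mean *and* variance to zero —
asks how well the data are explained when that deviation is disallowed.
For a zero-variance pin, the change in log evidence is the
Savage–Dickey density ratio

    dF = log q(theta_S = 0) - log p(theta_S = 0)

between the posterior and prior marginals at the pinned value, and the
reduced posterior is the conditional of the full posterior on that
value.  Reduced priors with positive variance use the general
closed-form Gaussian reduction.  Free energies are converted to model
probabilities by a softmax under uniform model priors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .inversion import GaussianBelief

__all__ = [
    "ComparisonResult",
    "pin_parameter",
    "bayesian_model_reduction",
    "model_probabilities",
]


@dataclass
class ComparisonResult:
    """Relative free energies and probabilities of a set of models."""

    labels: tuple
    free_energies: np.ndarray  # relative: minimum shifted to 0
    probabilities: np.ndarray
    winner: str
    losing_probability: float
    raw_free_energies: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.free_energies = np.asarray(self.free_energies, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("model probabilities must sum to 1")
        if self.labels[int(np.argmax(self.free_energies))] != self.winner:
            raise ValueError("winner must have the maximum free energy")

    def probability(self, label: str) -> float:
        return float(self.probabilities[self.labels.index(label)])

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "free_energies_relative": self.free_energies.tolist(),
            "probabilities": self.probabilities.tolist(),
            "winner": self.winner,
            "losing_probability": self.losing_probability,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "model": list(self.labels),
                "F_relative": self.free_energies,
                "probability": self.probabilities,
            }
        ).to_csv(path, index=False)


def pin_parameter(prior: GaussianBelief, label: str) -> GaussianBelief:
    """Reduced prior with the named parameter pinned to zero.

    Sets the component's mean and variance to zero and removes its
    covariances with every other parameter.  Idempotent.
    """
    i = prior.index(label)
    mean = prior.mean.copy()
    cov = prior.cov.copy()
    mean[i] = 0.0
    cov[i, :] = 0.0
    cov[:, i] = 0.0
    return GaussianBelief(names=prior.names, mean=mean, cov=cov)


def _pinned_indices(prior: GaussianBelief, reduced_prior: GaussianBelief) -> np.ndarray:
    full_var = np.diag(prior.cov)
    red_var = np.diag(reduced_prior.cov)
    return np.flatnonzero((red_var == 0.0) & (full_var > 0.0))


def _gaussian_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    d = len(x)
    r = x - mean
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular marginal covariance")
    return float(-0.5 * (d * math.log(2 * math.pi) + logdet
                         + r @ np.linalg.solve(cov, r)))


def _savage_dickey(
    posterior: GaussianBelief,
    prior: GaussianBelief,
    reduced_prior: GaussianBelief,
    pinned: np.ndarray,
) -> tuple[float, GaussianBelief]:
    names = posterior.names
    d = len(names)
    keep = np.setdiff1d(np.arange(d), pinned)
    # the reduction must leave the un-pinned prior block untouched and
    # the full prior must not correlate pinned with kept parameters,
    # otherwise the density-ratio shortcut does not apply
    if keep.size:
        if not np.allclose(reduced_prior.cov[np.ix_(keep, keep)],
                           prior.cov[np.ix_(keep, keep)], atol=1e-12) or \
           not np.allclose(reduced_prior.mean[keep], prior.mean[keep], atol=1e-12):
            raise ValueError(
                "zero-variance reduction requires the un-pinned prior block "
                "to be unchanged"
            )
        if not np.allclose(prior.cov[np.ix_(pinned, keep)], 0.0, atol=1e-12):
            raise ValueError(
                "zero-variance reduction requires a prior with no "
                "pinned/un-pinned covariance"
            )
    v = reduced_prior.mean[pinned]  # pin value (zero for pin_parameter)
    delta_f = (
        _gaussian_logpdf(v, posterior.mean[pinned],
                         posterior.cov[np.ix_(pinned, pinned)])
        - _gaussian_logpdf(v, prior.mean[pinned],
                           prior.cov[np.ix_(pinned, pinned)])
    )
    # reduced posterior = conditional of the full posterior at the pin
    mean = np.zeros(d)
    cov = np.zeros((d, d))
    mean[pinned] = v
    if keep.size:
        s_kk = posterior.cov[np.ix_(keep, keep)]
        s_ks = posterior.cov[np.ix_(keep, pinned)]
        s_ss = posterior.cov[np.ix_(pinned, pinned)]
        sol = np.linalg.solve(s_ss, (v - posterior.mean[pinned]))
        mean[keep] = posterior.mean[keep] + s_ks @ sol
        cond = s_kk - s_ks @ np.linalg.solve(s_ss, s_ks.T)
        cov[np.ix_(keep, keep)] = 0.5 * (cond + cond.T)
    reduced_post = GaussianBelief(names=names, mean=mean, cov=cov)
    return float(delta_f), reduced_post


def _general_reduction(
    posterior: GaussianBelief,
    prior: GaussianBelief,
    reduced_prior: GaussianBelief,
) -> tuple[float, GaussianBelief]:
    """Closed-form Gaussian reduction for non-degenerate reduced priors.

    With precisions Pq (posterior), Pp (prior) and Pr (reduced prior),
    the reduced posterior has precision  Pq + Pr - Pp  and

        dF = 1/2 [ log|Pr| - log|Pp| + log|Pq| - log|Ps| ]
           + 1/2 [ ms' Ps ms - mq' Pq mq + mp' Pp mp - mr' Pr mr ]

    where ``Ps, ms`` are the reduced-posterior precision and mean.
    """
    pq = np.linalg.inv(posterior.cov)
    pp = np.linalg.inv(prior.cov)
    pr = np.linalg.inv(reduced_prior.cov)
    ps = pq + pr - pp
    eta = pq @ posterior.mean + pr @ reduced_prior.mean - pp @ prior.mean
    cov_s = np.linalg.inv(ps)
    cov_s = 0.5 * (cov_s + cov_s.T)
    ms = cov_s @ eta

    def logdet(mat):
        sign, ld = np.linalg.slogdet(mat)
        if sign <= 0:
            raise np.linalg.LinAlgError("indefinite precision in model reduction")
        return ld

    delta_f = 0.5 * (logdet(pr) - logdet(pp) + logdet(pq) - logdet(ps)) + 0.5 * (
        ms @ ps @ ms
        - posterior.mean @ pq @ posterior.mean
        + prior.mean @ pp @ prior.mean
        - reduced_prior.mean @ pr @ reduced_prior.mean
    )
    reduced_post = GaussianBelief(names=posterior.names, mean=ms, cov=cov_s)
    return float(delta_f), reduced_post


def bayesian_model_reduction(
    posterior: GaussianBelief,
    prior: GaussianBelief,
    reduced_prior: GaussianBelief,
) -> tuple[float, GaussianBelief]:
    """Re-score a fitted model under a reduced prior without refitting.

    Returns ``(delta_f, reduced_posterior)`` where ``delta_f`` is the
    change in log evidence; the reduced model's evidence is
    ``posterior.free_energy + delta_f``.  Zero-variance pins use the
    Savage–Dickey ratio; positive-variance reductions use the general
    Gaussian formula.
    """
    if posterior.names != prior.names or posterior.names != reduced_prior.names:
        raise ValueError("posterior, prior and reduced prior labels differ")
    if np.allclose(reduced_prior.mean, prior.mean, atol=0) and np.allclose(
        reduced_prior.cov, prior.cov, atol=0
    ):
        return 0.0, posterior
    pinned = _pinned_indices(prior, reduced_prior)
    if pinned.size:
        delta_f, reduced_post = _savage_dickey(posterior, prior, reduced_prior, pinned)
    else:
        delta_f, reduced_post = _general_reduction(posterior, prior, reduced_prior)
    if posterior.free_energy is not None:
        reduced_post.free_energy = posterior.free_energy + delta_f
    return delta_f, reduced_post


def model_probabilities(free_energies) -> ComparisonResult:
    """Softmax conversion of model free energies to posterior probabilities.

    Accepts a mapping ``{label: F}`` or a sequence of ``(label, F)``
    pairs; assumes a uniform prior over models.  Free energies are
    reported relative to the minimum (the lowest-evidence model sits at
    zero); the losing probability is ``1 - p(winner)``.
    """
    if isinstance(free_energies, dict):
        items = list(free_energies.items())
    else:
        items = list(free_energies)
    if len(items) < 2:
        raise ValueError("model comparison needs at least two models")
    labels = tuple(lbl for lbl, _ in items)
    f = np.array([float(v) for _, v in items])
    if not np.all(np.isfinite(f)):
        raise ValueError("free energies must be finite")
    z = f - f.max()
    p = np.exp(z)
    p /= p.sum()
    winner = labels[int(np.argmax(f))]
    return ComparisonResult(
        labels=labels,
        free_energies=f - f.min(),
        probabilities=p,
        winner=winner,
        losing_probability=float(1.0 - p.max()),
        raw_free_energies=f,
    )
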