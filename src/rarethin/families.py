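"""Likelihood kernels for the three count families used by the density GAMs.

* negative binomial (NB2: variance mu + mu^2/theta),
* Tweedie compound Poisson-gamma with power parameter 1 < p < 2
  (positive mass at zero, continuous density on the positives),
* zero-inflated Poisson whose presence probability is a logit-scaled
  function of the density linear predictor (the mgcv-style `ziP` link):
  pi = inverse-logit(theta0 + exp(theta1) * eta), so presence probability
  never decreases with predicted density.

The Tweedie density is evaluated by the interpolated series expansion
around the dominant term (the standard stable evaluation for compound
Poisson-gamma densities); everything else reduces to closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "NegBinParams",
    "TweedieParams",
    "ZipParams",
    "nb_logpmf",
    "tweedie_logdensity",
    "tweedie_log_zero_mass",
    "zip_logpmf",
    "zip_presence_prob",
    "sample_negbin",
    "sample_tweedie",
    "sample_zip",
    "sample_zt_negbin",
]


@dataclass(frozen=True)
class NegBinParams:
    mu: float
    theta: float

    def __post_init__(self):
        if not (self.mu > 0):
            raise ValueError("mu must be > 0")
        if not (self.theta > 0):
            raise ValueError("theta must be > 0")


@dataclass(frozen=True)
class TweedieParams:
    mu: float
    power_p: float
    phi: float

    def __post_init__(self):
        if not (self.mu > 0):
            raise ValueError("mu must be > 0")
        if not (1.0 < self.power_p < 2.0):
            raise ValueError("power p must lie in (1, 2)")
        if not (self.phi > 0):
            raise ValueError("phi must be > 0")


@dataclass(frozen=True)
class ZipParams:
    """eta is the (log-scale) linear predictor of the Poisson mean."""

    eta: float
    theta0: float
    theta1: float

    @property
    def lam(self) -> float:
        return float(np.exp(self.eta))

    @property
    def pi(self) -> float:
        return float(special.expit(self.theta0 + np.exp(self.theta1) * self.eta))


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    if not np.allclose(y, np.round(y)):
        raise ValueError("counts must be integers")
    return y.astype(float)


def nb_logpmf(y, params: NegBinParams):
    """Log-pmf of NB2 with mean mu and size theta."""
    y = _check_counts(y)
    n = params.theta
    p = params.theta / (params.theta + params.mu)
    return stats.nbinom.logpmf(y, n, p)


def tweedie_log_zero_mass(mu, power_p, phi):
    """log P(Y = 0) = -mu^(2-p) / (phi * (2-p)); exact for 1 < p < 2."""
    mu = np.asarray(mu, dtype=float)
    return -(mu ** (2.0 - power_p)) / (phi * (2.0 - power_p))


def _tweedie_log_series(y, power_p, phi):
    """log of the normalising series a(y, phi) = (1/y) * sum_j W_j, y > 0.

    W_j = y^(j a) / ((p-1)^(j a) phi^(j(1+a)) (2-p)^j j! Gamma(j a)),
    a = (2-p)/(p-1).  Terms are summed in log space over a window around
    the dominant index j* ~ y^(2-p) / ((2-p) phi).
    """
    y = np.asarray(y, dtype=float)
    p = power_p
    alpha = (2.0 - p) / (p - 1.0)
    jmax = np.maximum(y ** (2.0 - p) / ((2.0 - p) * phi), 1.0)
    hi = int(np.ceil(np.max(jmax + 12.0 * np.sqrt(jmax) + 25.0)))
    j = np.arange(1, hi + 1, dtype=float)
    logy = np.log(y)[:, None]
    logw = (
        j * alpha * logy
        - j * alpha * np.log(p - 1.0)
        - j * (1.0 + alpha) * np.log(phi)
        - j * np.log(2.0 - p)
        - special.gammaln(j + 1.0)
        - special.gammaln(j * alpha)
    )
    return special.logsumexp(logw, axis=1) - np.log(y)


def tweedie_logdensity(y, params: TweedieParams):
    """Log-density of the compound Poisson-gamma Tweedie.

    Returns the log point mass at y == 0 and the log continuous density at
    y > 0.  Accepts scalars or arrays.
    """
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    if np.any(y < 0):
        raise ValueError("y must be nonnegative")
    mu, p, phi = params.mu, params.power_p, params.phi
    out = np.empty_like(y)
    zero = y == 0
    out[zero] = tweedie_log_zero_mass(mu, p, phi)
    if np.any(~zero):
        yp = y[~zero]
        # exponential-dispersion part: (y theta - kappa(theta)) / phi
        tilt = (
            yp * mu ** (1.0 - p) / (1.0 - p) - mu ** (2.0 - p) / (2.0 - p)
        ) / phi
        out[~zero] = _tweedie_log_series(yp, p, phi) + tilt
    return float(out[0]) if scalar else out


def zip_presence_prob(eta, theta0, theta1):
    """pi = inverse-logit(theta0 + exp(theta1) * eta); nondecreasing in eta."""
    return special.expit(theta0 + np.exp(theta1) * np.asarray(eta, dtype=float))


def zip_logpmf(y, params: ZipParams):
    """Log-pmf of the zero-inflated Poisson mixture.

    P(0) = (1 - pi) + pi e^(-lam);  P(k >= 1) = pi * Poisson(k; lam).
    """
    y = _check_counts(y)
    lam, pi = params.lam, params.pi
    with np.errstate(divide="ignore"):  # log terms in the unused branch
        out = np.where(
            y == 0,
            np.logaddexp(np.log1p(-pi), np.log(pi) - lam),
            np.log(pi) + stats.poisson.logpmf(np.maximum(y, 1), lam),
        )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# samplers (used by the synthetic-data generator and Monte-Carlo checks)
# ---------------------------------------------------------------------------

def sample_negbin(rng: np.random.Generator, mu, theta, size=None):
    """NB2 draws via the Poisson-gamma mixture."""
    g = rng.gamma(shape=theta, scale=np.asarray(mu, dtype=float) / theta, size=size)
    return rng.poisson(g)


def sample_tweedie(rng: np.random.Generator, mu, power_p, phi, size=None):
    """Compound Poisson-gamma draws matching ``tweedie_logdensity``."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size if size else np.shape(mu))
    p = power_p
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    shape = (2.0 - p) / (p - 1.0)
    scale = phi * (p - 1.0) * mu ** (p - 1.0)
    n = rng.poisson(lam)
    out = np.zeros_like(mu, dtype=float)
    pos = n > 0
    out[pos] = rng.gamma(shape * n[pos], scale[pos] if scale.ndim else scale)
    return out


def sample_zip(rng: np.random.Generator, eta, theta0, theta1, size=None):
    """Zero-inflated Poisson draws under the logit-scaled presence link."""
    eta = np.broadcast_to(np.asarray(eta, dtype=float), size if size else np.shape(eta))
    pi = zip_presence_prob(eta, theta0, theta1)
    z = rng.random(eta.shape) < pi
    return np.where(z, rng.poisson(np.exp(eta)), 0)


def sample_zt_negbin(rng: np.random.Generator, mean, theta, size):
    """Zero-truncated NB2 group sizes with the *truncated* mean ``mean``.

    The underlying NB mean is solved so that E[Y | Y >= 1] equals the
    requested mean, then zeros are rejected.
    """
    from scipy.optimize import brentq

    def trunc_mean(mu):
        p0 = np.exp(stats.nbinom.logpmf(0, theta, theta / (theta + mu)))
        return mu / (1.0 - p0)

    if mean <= 1.0:
        raise ValueError("zero-truncated mean must exceed 1")
    mu = brentq(lambda m: trunc_mean(m) - mean, 1e-9, mean * 10.0)
    out = np.asarray(sample_negbin(rng, mu, theta, size=size))
    while True:
        zero = out == 0
        if not zero.any():
            break
        out[zero] = sample_negbin(rng, mu, theta, size=int(zero.sum()))
    return out
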