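"""Compound Poisson-gamma (Tweedie) distribution for index 1 < p < 2.

A Tweedie variable with mean ``mu``, dispersion ``phi`` and index ``p`` in
(1, 2) has variance ``phi * mu**p`` and is distributed as a Poisson sum of
iid gamma variates: continuous on (0, inf) with an atom at zero.  This is
the observation model for averaged winter count data: right-skewed
positive values with a point mass at exact zero, in a single family.

The density for y > 0 is evaluated by the Dunn-Smyth series expansion of
the exponential-dispersion-model normaliser; the series is truncated
adaptively around its largest term so the dropped tail is negligible at
double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import logc_array
from .errors import SeriesConvergenceError, TweedieDomainError

#: half-width kept clear of the p in (1, 2) boundaries inside samplers
P_EDGE = 1e-3


@dataclass(frozen=True)
class TweedieParams:
    """Mean / dispersion / index triple (mu, phi, p) with 1 < p < 2."""

    mu: float
    phi: float
    p: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise TweedieDomainError(f"mu must be positive, got {self.mu}")
        if not (self.phi > 0):
            raise TweedieDomainError(f"phi must be positive, got {self.phi}")
        if not (1.0 < self.p < 2.0):
            raise TweedieDomainError(
                f"index p must lie in the open interval (1, 2), got {self.p}"
            )


@dataclass(frozen=True)
class CompoundPoissonForm:
    """Equivalent (Poisson rate, gamma shape, gamma scale) parameterisation."""

    lam: float
    shape: float
    scale: float


def to_compound_poisson(params: TweedieParams) -> CompoundPoissonForm:
    """Map (mu, phi, p) to the compound Poisson-gamma parameters.

    lam   = mu^(2-p) / (phi*(2-p))   Poisson rate of gamma summands
    shape = (2-p)/(p-1)              gamma shape of each summand
    scale = phi*(p-1)*mu^(p-1)       gamma scale of each summand

    so that lam*shape*scale == mu.  Raises near the p boundaries, where
    the shape (p -> 2) or the rate (p -> 1) degenerates.
    """
    mu, phi, p = params.mu, params.phi, params.p
    if p >= 2.0 - P_EDGE or p <= 1.0 + P_EDGE:
        raise TweedieDomainError(
            f"p={p} is within {P_EDGE} of the (1,2) boundary; the compound "
            "Poisson representation degenerates there"
        )
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    shape = (2.0 - p) / (p - 1.0)
    scale = phi * (p - 1.0) * mu ** (p - 1.0)
    return CompoundPoissonForm(lam=lam, shape=shape, scale=scale)


def log_zero_mass(params: TweedieParams) -> float:
    """log P(Y = 0) = -lam = -mu^(2-p)/(phi*(2-p))."""
    mu, phi, p = params.mu, params.phi, params.p
    return -(mu ** (2.0 - p)) / (phi * (2.0 - p))


def log_normalizer(y: np.ndarray, phi: float, p: float) -> np.ndarray:
    """log c(y; phi, p), the mu-free series factor of the density.

    Entries with y == 0 get 0 (their whole log-density is the tilt term).
    Used directly by the MCMC engine, which caches it across mean updates.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    with np.errstate(divide="ignore"):
        logy = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), 0.0)
    out = np.empty_like(y)
    ok = logc_array(y, logy, float(phi), float(p), out)
    if not ok or np.isnan(out).any():
        raise SeriesConvergenceError(
            f"Tweedie series did not converge for phi={phi}, p={p}"
        )
    return out


def log_density(y, params: TweedieParams):
    """Log density/mass of the Tweedie distribution at y >= 0.

    For y == 0 this is the log of the discrete zero mass; for y > 0 the log
    of the continuous density.  Accepts scalars or arrays.
    """
    arr = np.atleast_1d(np.asarray(y, dtype=np.float64))
    if (arr < 0).any():
        raise TweedieDomainError("y must be non-negative")
    mu, phi, p = params.mu, params.phi, params.p
    logc = log_normalizer(arr, phi, p)
    theta_y = arr * mu ** (1.0 - p) / (1.0 - p)
    kappa = mu ** (2.0 - p) / (2.0 - p)
    out = logc + (theta_y - kappa) / phi
    if np.isscalar(y) or np.ndim(y) == 0:
        return float(out[0])
    return out


def sample(params: TweedieParams, n: int, seed) -> np.ndarray:
    """Draw n variates as N ~ Poisson(lam), Y = Gamma(N*shape, scale).

    ``seed`` may be an int or a numpy Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    form = to_compound_poisson(params)
    counts = rng.poisson(form.lam, size=n)
    out = np.zeros(n)
    pos = counts > 0
    # a gamma sum with N summands collapses to shape N*alpha
    out[pos] = rng.gamma(counts[pos] * form.shape, form.scale)
    return out


def sample_matrix(mu: np.ndarray, phi: float, p: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorised draws with elementwise means (used by GOF replicates)."""
    mu = np.asarray(mu, dtype=np.float64)
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    shape = (2.0 - p) / (p - 1.0)
    scale = phi * (p - 1.0) * mu ** (p - 1.0)
    counts = rng.poisson(lam)
    out = np.zeros(mu.shape)
    pos = counts > 0
    out[pos] = rng.gamma(counts[pos] * shape, scale[pos])
    return out


def unit_deviance(y, mu, p: float):
    """Tweedie unit deviance for 1 < p < 2, finite at y = 0.

    d(y, mu) = 2*( y^(2-p)/((1-p)(2-p)) - y*mu^(1-p)/(1-p) + mu^(2-p)/(2-p) )
    """
    if not (1.0 < p < 2.0):
        raise TweedieDomainError(f"index p must lie in (1, 2), got {p}")
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    if (y < 0).any() or (mu <= 0).any():
        raise TweedieDomainError("require y >= 0 and mu > 0")
    val = 2.0 * (
        np.power(y, 2.0 - p) / ((1.0 - p) * (2.0 - p))
        - y * np.power(mu, 1.0 - p) / (1.0 - p)
        + np.power(mu, 2.0 - p) / (2.0 - p)
    )
    # clip the tiny negative round-off at y == mu
    val = np.maximum(val, 0.0)
    return float(val) if val.ndim == 0 else val
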