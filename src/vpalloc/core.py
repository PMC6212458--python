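"""Core variable-precision (VP) generative model.

Precision J is the inverse variance *per axis* of the 2-D isotropic Gaussian
report distribution (units dva^-2), so the per-axis standard deviation is
J**-0.5.  Across trials J is gamma-distributed with mean ``Jbar`` and scale
``tau`` (shape k = Jbar / tau).  The Euclidean estimation error eps (dva) of
an isotropic 2-D Gaussian deviate is then Rayleigh given J, and the marginal
error density is the gamma mixture of Rayleighs, evaluated here by quadrature
over J (a closed form exists and is used as an independent oracle in the test
suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special, stats


@lru_cache(maxsize=32)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)

__all__ = [
    "PrecisionDistribution",
    "IntegrationGrid",
    "precision_grid",
    "rayleigh_error_pdf",
    "marginal_error_pdf",
    "expected_error_power",
    "sample_error",
    "DivergentLossError",
]

# Below this J the Rayleigh density at any behaviorally relevant eps is
# numerically zero; clipping the quadrature range here avoids float underflow
# for extremely small gamma shapes without measurable density error.
_J_FLOOR = 1e-280


class DivergentLossError(ValueError):
    """Expected loss E[eps**beta] diverges: gamma shape k = Jbar/tau <= beta/2."""


@dataclass(frozen=True)
class PrecisionDistribution:
    """Gamma distribution of memory precision: mean ``Jbar``, scale ``tau``.

    Parameters
    ----------
    Jbar : float
        Mean precision (dva^-2).  Must be positive.
    tau : float
        Gamma scale parameter (dva^-2).  Must be positive.  The shape is
        ``k = Jbar / tau``; larger ``tau`` means more trial-to-trial
        variability in memory quality at fixed mean.
    """

    Jbar: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.Jbar > 0 and np.isfinite(self.Jbar)):
            raise ValueError(f"Jbar must be positive and finite, got {self.Jbar}")
        if not (self.tau > 0 and np.isfinite(self.tau)):
            raise ValueError(f"tau must be positive and finite, got {self.tau}")

    @property
    def shape(self) -> float:
        """Gamma shape k = Jbar / tau (dimensionless)."""
        return self.Jbar / self.tau


@dataclass(frozen=True)
class IntegrationGrid:
    """Quadrature rule over precision J: nodes (dva^-2) and weights.

    Weights include the gamma probability density, so for any function g,
    ``weights @ g(nodes)`` approximates E[g(J)].
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.nodes.size == 0:
            raise ValueError("empty integration grid")
        if self.nodes.shape != self.weights.shape:
            raise ValueError("nodes and weights must have matching shapes")


def precision_grid(
    dist: PrecisionDistribution,
    n_nodes: int = 500,
    tail_mass: float = 1e-10,
) -> IntegrationGrid:
    """Build a Gauss-Legendre quadrature rule in log J for a gamma precision law.

    Nodes are placed between the ``tail_mass/2`` and ``1 - tail_mass/2``
    gamma quantiles, log-spaced via the change of variable u = log J (the
    integrand is analytic in u, so the rule converges exponentially).  A
    warning is raised when the excluded tail mass exceeds 1e-4 — this only
    happens when float underflow forces the lower bound above the target
    quantile (tiny shapes); the excluded region contributes density bounded
    by ``J_floor * eps`` and is negligible in practice.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    k = dist.shape
    tau = dist.tau
    # The left bound must cover not just the gamma mass but the peak of the
    # mixture integrand for large errors, which sits at small J.  The gamma
    # CDF behaves as (J/tau)^k / Gamma(k+1) near 0, so the quantile at mass m
    # is tau * exp((log m + gammaln(k+1)) / k); extend to m ~ 1e-250.
    lo_mass = stats.gamma.ppf(tail_mass / 2, k, scale=tau)
    lo_deep = tau * float(special.gammaincinv(k, 1e-250))
    if not (np.isfinite(lo_deep) and lo_deep > 0):
        # underflowed inverse (tiny shapes): asymptotic quantile from
        # F(J) ~ (J/tau)^k / Gamma(k+1)
        lo_deep = tau * np.exp((np.log(1e-250) + special.gammaln(k + 1)) / k)
    lo = min(lo_mass, lo_deep) if np.isfinite(lo_deep) else lo_mass
    hi = stats.gamma.isf(tail_mass / 2, k, scale=tau)
    lo = max(lo, _J_FLOOR)
    excluded = special.gammainc(k, lo / tau) + special.gammaincc(k, hi / tau)
    if excluded > 1e-4 and lo > _J_FLOOR * 10:
        warnings.warn(
            f"precision grid excludes gamma tail mass {excluded:.2e} "
            f"(Jbar={dist.Jbar:g}, tau={dist.tau:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    u, w = _leggauss(n_nodes)
    a, b = np.log(lo), np.log(hi)
    uu = 0.5 * (b - a) * u + 0.5 * (b + a)
    J = np.exp(uu)
    # Jacobian dJ = J du; log-space gamma pdf avoids over/underflow at
    # extreme shapes: pdf(J) * J = exp(k*log(J/tau) - J/tau - gammaln(k))
    log_pdf_J = k * (uu - np.log(tau)) - J / tau - special.gammaln(k)
    weights = w * 0.5 * (b - a) * np.exp(log_pdf_J)
    return IntegrationGrid(nodes=J, weights=weights)


def rayleigh_error_pdf(eps, J):
    """Density of the Euclidean error eps given precision J.

    The report is drawn from an isotropic 2-D Gaussian with per-axis variance
    1/J; the norm of the deviation is Rayleigh with scale J**-0.5:
    ``f(eps | J) = J * eps * exp(-J * eps**2 / 2)``.

    Parameters are broadcast; returns density in dva^-1.
    """
    eps = np.asarray(eps, dtype=float)
    J = np.asarray(J, dtype=float)
    if np.any(eps < 0):
        raise ValueError("error magnitude eps must be >= 0")
    if np.any(J <= 0):
        raise ValueError("precision J must be > 0")
    return J * eps * np.exp(-J * eps**2 / 2.0)


def marginal_error_pdf(eps, dist: PrecisionDistribution, grid: IntegrationGrid | None = None):
    """Marginal error density p(eps | Jbar, tau) = E_J[f(eps | J)] by quadrature.

    ``grid`` defaults to :func:`precision_grid` for ``dist``.  ``eps`` may be
    a scalar or array; the return matches its shape.
    """
    if grid is None:
        grid = precision_grid(dist)
    eps = np.asarray(eps, dtype=float)
    if np.any(eps < 0):
        raise ValueError("error magnitude eps must be >= 0")
    scalar = eps.ndim == 0
    e = np.atleast_1d(eps)
    # (n_nodes, n_eps) Rayleigh matrix, weighted by gamma mass
    f = rayleigh_error_pdf(e[None, :], grid.nodes[:, None])
    out = grid.weights @ f
    return float(out[0]) if scalar else out


def expected_error_power(dist: PrecisionDistribution, beta: float) -> float:
    """Expected loss E[eps**beta] under the VP model (closed form).

    For eps | J Rayleigh and J ~ Gamma(k, tau),
    ``E[eps**beta] = 2**(beta/2) * Gamma(1 + beta/2) * tau**(-beta/2)
    * Gamma(k - beta/2) / Gamma(k)``, finite only when k > beta/2.

    Raises
    ------
    DivergentLossError
        When k = Jbar/tau <= beta/2 (the gamma left tail makes the moment
        infinite).
    """
    if beta < 0:
        raise ValueError("loss exponent beta must be >= 0")
    if beta == 0:
        return 1.0
    k = dist.shape
    if k <= beta / 2:
        raise DivergentLossError(
            f"E[eps^beta] diverges: shape k={k:g} <= beta/2={beta / 2:g}"
        )
    log_val = (
        (beta / 2) * np.log(2.0)
        + special.gammaln(1 + beta / 2)
        - (beta / 2) * np.log(dist.tau)
        + special.gammaln(k - beta / 2)
        - special.gammaln(k)
    )
    return float(np.exp(log_val))


def sample_error(
    dist: PrecisionDistribution,
    n: int = 1,
    rng: np.random.Generator | int | None = None,
):
    """Draw (J, 2-D endpoint offset) pairs from the VP generative process.

    J ~ Gamma(k, tau); offset ~ isotropic Gaussian with per-axis sd J**-0.5.
    Returns ``(J, offsets)`` with shapes (n,) and (n, 2).  Reproducible when
    ``rng`` is an integer seed or a seeded Generator.
    """
    rng = np.random.default_rng(rng)
    J = rng.gamma(shape=dist.shape, scale=dist.tau, size=n)
    offsets = rng.standard_normal((n, 2)) / np.sqrt(J)[:, None]
    return J, offsets
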