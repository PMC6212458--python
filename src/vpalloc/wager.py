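"""Post-decision wager model: payoff, hit probability, expected utility, softmax.

After the saccade, the observer wagers on memory fidelity by sizing a circle
centered on the saccade endpoint.  A hit (true target inside the circle)
earns ``alpha * exp(-gamma_decay * r)`` points; a miss earns nothing.  Since
the endpoint-target distance is Rayleigh with scale J**-0.5, the hit
probability is the Rayleigh CDF.  The observer knows the trial's precision J
and chooses the radius noisily: response mass is a softmax of expected
utility with temperature ``lam`` over a discrete radius grid (the screen
bounds responses, and a finite set makes normalization exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "PayoffRule",
    "RadiusGrid",
    "points",
    "hit_probability",
    "expected_utility",
    "softmax_radius_density",
    "optimal_radius",
]


@dataclass(frozen=True)
class PayoffRule:
    """Exponential points schedule: ``alpha * exp(-gamma_decay * r)`` on a hit.

    Defaults are the task's values: 120 points at radius zero, decaying at
    0.4 per dva of radius.
    """

    alpha: float = 120.0
    gamma_decay: float = 0.4

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.gamma_decay <= 0:
            raise ValueError("alpha and gamma_decay must be positive")


@dataclass(frozen=True)
class RadiusGrid:
    """Discrete set of candidate wager radii (dva), default 0.1-10 by 0.05."""

    r_min: float = 0.1
    r_max: float = 10.0
    step: float = 0.05
    values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0 <= self.r_min < self.r_max) or self.step <= 0:
            raise ValueError("require 0 <= r_min < r_max and step > 0")
        n = int(round((self.r_max - self.r_min) / self.step)) + 1
        vals = self.r_min + self.step * np.arange(n)
        object.__setattr__(self, "values", vals)

    def snap(self, r, tol: float = 1e-6):
        """Indices of the nearest grid nodes; warns when r is off-grid by > tol."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        idx = np.clip(
            np.round((r - self.r_min) / self.step).astype(int), 0, len(self.values) - 1
        )
        off = np.abs(self.values[idx] - r)
        if np.any(off > tol):
            import warnings

            warnings.warn(
                f"{int(np.sum(off > tol))} radius value(s) off-grid by up to "
                f"{off.max():.3g} dva; snapped to nearest node",
                RuntimeWarning,
                stacklevel=2,
            )
        return idx


def points(r, payoff: PayoffRule = PayoffRule()):
    """Points earned for a hit with circle radius r: alpha * exp(-gamma_decay * r)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    return payoff.alpha * np.exp(-payoff.gamma_decay * r)


def hit_probability(r, J):
    """Probability the true target lies inside a radius-r circle at the endpoint.

    The endpoint-target distance is Rayleigh with scale J**-0.5, so
    ``P(hit) = 1 - exp(-J * r**2 / 2)``.
    """
    r = np.asarray(r, dtype=float)
    J = np.asarray(J, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    if np.any(J <= 0):
        raise ValueError("precision J must be > 0")
    return -np.expm1(-J * r**2 / 2.0)


def expected_utility(r, J, payoff: PayoffRule = PayoffRule()):
    """Expected points for radius r at precision J: points(r) * P(hit | r, J)."""
    return points(r, payoff) * hit_probability(r, J)


def optimal_radius(J, payoff: PayoffRule = PayoffRule(), rgrid: RadiusGrid | None = None):
    """Radius maximizing expected utility, restricted to the response grid."""
    if rgrid is None:
        rgrid = RadiusGrid()
    J = np.atleast_1d(np.asarray(J, dtype=float))
    eu = expected_utility(rgrid.values[None, :], J[:, None], payoff)
    r_star = rgrid.values[np.argmax(eu, axis=1)]
    return r_star if r_star.size > 1 else float(r_star[0])


def softmax_radius_density(
    J: float,
    lam: float,
    payoff: PayoffRule = PayoffRule(),
    rgrid: RadiusGrid | None = None,
) -> np.ndarray:
    """Softmax response mass over the radius grid: P(r) ∝ exp(EU(r; J) / lam).

    ``lam`` (points) is the decision-noise temperature: lam -> 0 concentrates
    all mass on the EU maximizer, lam -> inf approaches uniform.  Returns a
    probability vector over ``rgrid.values`` summing to 1.
    """
    if lam <= 0:
        raise ValueError("decision noise lam must be > 0")
    if rgrid is None:
        rgrid = RadiusGrid()
    eu = expected_utility(rgrid.values, J, payoff)
    return special.softmax(eu / lam)


def softmax_radius_matrix(
    J_nodes: np.ndarray,
    lam: float,
    payoff: PayoffRule = PayoffRule(),
    rgrid: RadiusGrid | None = None,
) -> np.ndarray:
    """Row-stochastic matrix of softmax radius mass, one row per precision node."""
    if lam <= 0:
        raise ValueError("decision noise lam must be > 0")
    if rgrid is None:
        rgrid = RadiusGrid()
    eu = expected_utility(rgrid.values[None, :], np.asarray(J_nodes)[:, None], payoff)
    return special.softmax(eu / lam, axis=1)
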