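"""Resource-allocation strategies over priority conditions.

Total memory resource ``Jbar_total`` is split across the probed priority
conditions as a proportion vector p on the simplex; condition i receives mean
precision ``p_i * Jbar_total``.  Four strategies are implemented:

* Proportional — p equals the probe probabilities.
* Flexible — p is free (fit from data).
* Minimizing Error (ME) — p minimizes the probe-probability-weighted expected
  estimation error raised to a power beta ("sensitivity to error").
* Maximizing Points (MP) — p maximizes the probe-probability-weighted
  expected wager points, assuming a noiseless inner choice of circle radius.

The zero-probability condition is never probed and receives no resource; the
simplex covers the three probed conditions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from vpalloc.core import PrecisionDistribution, expected_error_power, precision_grid
from vpalloc.wager import PayoffRule, RadiusGrid, expected_utility

# Cache of optimal-wager value tables V(J) = max_r EU(r; J), which depend on
# the payoff rule and radius grid but on no fitted parameter.
_VALUE_TABLES: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _value_table(payoff: PayoffRule, rgrid: RadiusGrid, n: int = 4000):
    """Dense log-J table of the optimal expected wager value V(J)."""
    key = (payoff.alpha, payoff.gamma_decay, rgrid.r_min, rgrid.r_max, rgrid.step, n)
    if key not in _VALUE_TABLES:
        logJ = np.linspace(np.log(1e-12), np.log(1e8), n)
        J = np.exp(logJ)
        eu = expected_utility(rgrid.values[None, :], J[:, None], payoff)
        _VALUE_TABLES[key] = (logJ, eu.max(axis=1))
    return _VALUE_TABLES[key]

__all__ = [
    "ResourceBudget",
    "PROBE_PROBS",
    "proportional_allocation",
    "flexible_allocation",
    "minimize_error_allocation",
    "maximize_points_allocation",
    "me_objective",
    "mp_objective",
]

#: Probe probabilities of the three probed priority conditions (high, med, low).
PROBE_PROBS = np.array([0.6, 0.3, 0.1])


@dataclass(frozen=True)
class ResourceBudget:
    """Total mean precision ``Jbar_total`` and gamma scale ``tau`` (both dva^-2)."""

    Jbar_total: float
    tau: float

    def __post_init__(self) -> None:
        if self.Jbar_total <= 0 or self.tau <= 0:
            raise ValueError("Jbar_total and tau must be positive")


def _check_probs(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("probe probabilities must be a vector of length >= 2")
    if np.any(t <= 0) or np.any(t > 1):
        raise ValueError("probe probabilities must lie in (0, 1]")
    return t


def proportional_allocation(t=PROBE_PROBS) -> np.ndarray:
    """Allocate in proportion to probe probability: p = t / sum(t).

    Probabilities already summing to 1 (within float rounding) are returned
    verbatim, so the design's (0.6, 0.3, 0.1) maps to exactly itself.
    """
    t = _check_probs(t)
    s = t.sum()
    return t.copy() if abs(s - 1.0) < 1e-12 else t / s


def flexible_allocation(p_high: float, p_med: float) -> np.ndarray:
    """Free allocation from two proportions: p = (p_high, p_med, 1 - p_high - p_med)."""
    if p_high < 0 or p_med < 0:
        raise ValueError("proportions must be >= 0")
    if p_high + p_med > 1 + 1e-12:
        raise ValueError(f"p_high + p_med = {p_high + p_med:g} exceeds 1")
    return np.array([p_high, p_med, max(1.0 - p_high - p_med, 0.0)])


def me_objective(p, budget: ResourceBudget, beta: float, t) -> float:
    """ME loss: sum_i t_i * E[eps**beta] with mean precision p_i * Jbar_total."""
    p = np.asarray(p, dtype=float)
    total = 0.0
    for ti, pi in zip(np.asarray(t, dtype=float), p):
        d = PrecisionDistribution(pi * budget.Jbar_total, budget.tau)
        total += ti * expected_error_power(d, beta)
    return total


def mp_objective(
    p,
    budget: ResourceBudget,
    t,
    payoff: PayoffRule = PayoffRule(),
    rgrid: RadiusGrid | None = None,
    n_nodes: int = 200,
    interp: bool = False,
) -> float:
    """MP gain: sum_i t_i * E_J[max_r EU(r; J)], J ~ Gamma(p_i*Jbar_total/tau, tau).

    The inner maximization over the radius is noiseless (the planner picks the
    EU-optimal circle); the expectation over J uses gamma quadrature.  With
    ``interp=True`` the optimal wager value is read from a cached dense
    log-J table instead of being recomputed (fast path for nested fitting;
    interpolation error is far below the planner's convergence tolerance).
    """
    if rgrid is None:
        rgrid = RadiusGrid()
    p = np.asarray(p, dtype=float)
    if interp:
        return _mp_gain_interp(p, budget, t, payoff, rgrid, n_nodes)
    total = 0.0
    for ti, pi in zip(np.asarray(t, dtype=float), p):
        d = PrecisionDistribution(pi * budget.Jbar_total, budget.tau)
        grid = precision_grid(d, n_nodes=n_nodes)
        eu = expected_utility(rgrid.values[None, :], grid.nodes[:, None], payoff)
        v = eu.max(axis=1)  # value of the optimal wager at each precision
        total += ti * float(grid.weights @ v)
    return total


def _mp_gain_interp(p, budget, t, payoff, rgrid, n_nodes) -> float:
    """Fast MP gain: cached V(J) table + quadrature confined to where V varies.

    V(J) is ~0 below J ~ 1e-8 and saturates at the payoff ceiling above
    J ~ 1e6, so the quadrature only needs the intersection of that window
    with the gamma mass; the excluded tails enter as mass * V corrections.
    This stays accurate even for extreme gamma shapes (p at the floor),
    where mass spreads over hundreds of log units.
    """
    from scipy import special, stats

    from vpalloc.core import _leggauss

    logJ_tab, v_tab = _value_table(payoff, rgrid)
    u, w = _leggauss(n_nodes)
    tau = budget.tau
    total = 0.0
    for ti, pi in zip(np.asarray(t, dtype=float), p):
        k = pi * budget.Jbar_total / tau
        lo = max(stats.gamma.ppf(1e-12, k, scale=tau), 1e-8)
        hi = min(stats.gamma.isf(1e-12, k, scale=tau), 1e8)
        if lo >= hi:  # all mass on one side of the active window
            ev = float(np.interp(np.log(max(hi, 1e-300)), logJ_tab, v_tab))
            total += ti * ev
            continue
        a, b = np.log(lo), np.log(hi)
        uu = 0.5 * (b - a) * u + 0.5 * (b + a)
        J = np.exp(uu)
        log_pdf_J = k * (uu - np.log(tau)) - J / tau - special.gammaln(k)
        weights = w * 0.5 * (b - a) * np.exp(log_pdf_J)
        v = np.interp(uu, logJ_tab, v_tab)
        ev = float(weights @ v)
        # tail corrections: below lo V ~ V(lo) (downward-bounded by 0),
        # above hi V has saturated
        mass_lo = special.gammainc(k, lo / tau)
        mass_hi = special.gammaincc(k, hi / tau)
        ev += mass_lo * float(np.interp(a, logJ_tab, v_tab)) * 0.5
        ev += mass_hi * float(np.interp(b, logJ_tab, v_tab))
        total += ti * ev
    return total


def _simplex_starts(t: np.ndarray, lb: np.ndarray) -> list[np.ndarray]:
    """Deterministic interior multistart set, closed under permutation of t."""
    n = t.size
    starts = [np.full(n, 1.0 / n)]
    for power in (0.1, 0.25, 0.5, 1.0, 2.0, 4.0):
        s = t**power
        starts.append(s / s.sum())
    # one corner-leaning start per condition (permutation-closed set)
    for i in range(n):
        s = np.full(n, 0.1 / max(n - 1, 1))
        s[i] = 0.9
        starts.append(s / s.sum())
    out = []
    for s in starts:
        s = np.maximum(s, lb * 1.05)
        out.append(s / s.sum())
    return out


def _optimize_simplex(objective, n: int, lb: np.ndarray, starts, maximize: bool):
    """Multistart SLSQP over the simplex; returns the best (tie-broken) point.

    Free coordinates are p[:-1]; the last proportion is 1 - sum.  Ties within
    1e-9 relative objective are broken toward the lexicographically smallest
    allocation (only reachable in degenerate symmetric cases).
    """
    sign = -1.0 if maximize else 1.0

    def fun(x):
        p = np.append(x, 1.0 - x.sum())
        p = np.clip(p, lb, None)
        p = p / p.sum()
        return sign * objective(p)

    bounds = [(lb[i], 1.0 - lb[~np.isin(np.arange(n), [i])].sum()) for i in range(n - 1)]
    cons = [
        {"type": "ineq", "fun": lambda x: 1.0 - lb[-1] - x.sum()},
    ]
    candidates = []
    errors = []
    for s in starts:
        try:
            res = optimize.minimize(
                fun,
                s[:-1],
                method="SLSQP",
                bounds=bounds,
                constraints=cons,
                options={"maxiter": 200, "ftol": 1e-12},
            )
            x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
            p = np.append(x, 1.0 - x.sum())
            p = np.clip(p, lb, None)
            p = p / p.sum()
            candidates.append((fun(p[:-1]), p))
        except Exception as exc:  # pragma: no cover - defensive
            errors.append(exc)
    if not candidates:
        raise RuntimeError(f"all simplex optimizations failed: {errors}")
    fbest = min(c[0] for c in candidates)
    tol = 1e-9 * (1.0 + abs(fbest))
    tied = [p for f, p in candidates if f <= fbest + tol]
    tied.sort(key=lambda p: tuple(np.round(p, 9)))
    return tied[0]


def minimize_error_allocation(
    budget: ResourceBudget,
    beta: float,
    t=PROBE_PROBS,
    p_floor: float = 1e-3,
    n_starts: int = 10,
    starts=None,
) -> np.ndarray:
    """Allocation minimizing the probe-probability-weighted expected error power.

    Minimizes ``sum_i t_i * E[eps**beta | p_i * Jbar_total, tau]`` over the
    simplex.  Each proportion is bounded below by the larger of ``p_floor``
    and the finiteness bound ``beta * tau / (2 * Jbar_total)`` (the moment
    diverges at or below it).

    Raises
    ------
    ValueError
        If beta <= 0, or if the finiteness bounds are jointly infeasible
        (budget too small for finite expected loss at any allocation).
    """
    if beta <= 0:
        raise ValueError("loss exponent beta must be > 0")
    t = _check_probs(t)
    n = t.size
    k_bound = beta * budget.tau / (2.0 * budget.Jbar_total)
    lb = np.full(n, max(p_floor, k_bound * (1 + 1e-5)))
    if lb.sum() >= 1.0:
        raise ValueError(
            "infeasible: no allocation yields finite expected loss "
            f"(need each p_i > {k_bound:g} with {n} conditions)"
        )
    if starts is None:
        starts = _simplex_starts(t, lb)[: max(n_starts, 1)]
    else:
        starts = [np.clip(np.asarray(s, dtype=float), lb * 1.05, None) for s in starts]
        starts = [s / s.sum() for s in starts]

    def guarded(p):
        # the optimizer may probe points where a proportion dips below the
        # finiteness bound; a sloped finite penalty keeps it recoverable
        k = np.asarray(p) * budget.Jbar_total / budget.tau
        viol = beta / 2 - k.min()
        if viol > -1e-12 * beta:
            return 1e8 * (1.0 + max(viol, 0.0))
        return me_objective(p, budget, beta, t)

    return _optimize_simplex(guarded, n, lb, starts, maximize=False)


def maximize_points_allocation(
    budget: ResourceBudget,
    payoff: PayoffRule = PayoffRule(),
    t=PROBE_PROBS,
    p_floor: float = 1e-3,
    n_starts: int = 10,
    rgrid: RadiusGrid | None = None,
    n_nodes: int = 200,
    interp: bool = True,
    starts=None,
) -> np.ndarray:
    """Allocation maximizing expected wager points under the payoff rule.

    Maximizes ``sum_i t_i * E_J[max_r EU(r; J)]`` over the simplex.  At small
    budgets the optimum concentrates resource on high-priority items, pushing
    the low-priority share to the floor ("ignoring" those items).
    """
    t = _check_probs(t)
    n = t.size
    lb = np.full(n, p_floor)
    if starts is None:
        starts = _simplex_starts(t, lb)[: max(n_starts, 1)]
    else:
        starts = [np.clip(np.asarray(s, dtype=float), lb * 1.01, None) for s in starts]
        starts = [s / s.sum() for s in starts]
    return _optimize_simplex(
        lambda p: mp_objective(p, budget, t, payoff, rgrid, n_nodes, interp),
        n,
        lb,
        starts,
        maximize=True,
    )
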