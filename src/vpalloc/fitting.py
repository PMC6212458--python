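"""Maximum-likelihood fitting and model comparison.

Each model couples the VP generative core to one allocation strategy.  The
trial likelihood marginalizes the latent precision J by numerical
integration: for the estimation-only experiment (Exp. 1) the per-trial
likelihood is the marginal error density; for the wager experiment (Exp. 2)
error and circle radius share the trial's J, so the joint per-trial
likelihood is E_J[f(eps | J) * P(r | J, lam)] — the shared-J integral that
produces the within-priority error-radius correlation.

Fitting uses bounded multistart Nelder-Mead with Latin-hypercube starting
points (scale parameters sampled uniformly in log space); the reference
protocol for this task family uses 50 restarts, the desk-scale default
here is 10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from vpalloc.allocation import (
    PROBE_PROBS,
    ResourceBudget,
    flexible_allocation,
    maximize_points_allocation,
    minimize_error_allocation,
    proportional_allocation,
)
from vpalloc.core import (
    DivergentLossError,
    PrecisionDistribution,
    precision_grid,
    rayleigh_error_pdf,
)
from vpalloc.wager import PayoffRule, RadiusGrid, softmax_radius_matrix

__all__ = [
    "ModelSpec",
    "FitResult",
    "ComparisonResult",
    "loglik_exp1",
    "loglik_exp2",
    "fit_model",
    "information_criteria",
    "compare_models",
    "model_recovery",
    "DEFAULT_BOUNDS",
]

STRATEGIES = ("proportional", "flexible", "minimizing_error", "maximizing_points")

#: Generous, scale-appropriate default parameter bounds for ~10 dva targets.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "Jbar_total": (0.5, 500.0),  # dva^-2
    "tau": (0.1, 200.0),  # dva^-2
    "p_high": (0.01, 0.97),
    "p_med": (0.01, 0.97),
    "beta": (0.01, 5.0),  # loss exponent, bounded away from 0
    "lam": (0.01, 100.0),  # softmax temperature, points
}

#: Parameters whose plausible range spans orders of magnitude; starting
#: points are Latin-hypercube sampled uniformly in log10 of these.
_LOG_SCALE = {"Jbar_total", "tau", "lam"}

_LOG_FLOOR = 1e-300  # density clip; keeps -inf out of sums, flags stay honest


@dataclass
class ModelSpec:
    """A fittable model: experiment (1 or 2) x allocation strategy.

    Free parameters by strategy (Exp. 1 / Exp. 2):

    * proportional       — Jbar_total, tau            (2 / +lam = 3)
    * flexible           — + p_high, p_med            (4 / 5)
    * minimizing_error   — + beta                     (3 / 4)
    * maximizing_points  — Jbar_total, tau, lam       (Exp. 2 only, 3)

    ``planner_opts`` controls the inner simplex optimization used by the ME
    and MP strategies during likelihood evaluation; the defaults trade a
    little allocation precision (<~1e-3) for large fitting speedups.
    """

    experiment: int
    strategy: str
    probe_probs: tuple[float, ...] = (0.6, 0.3, 0.1)
    bounds: Mapping[str, tuple[float, float]] | None = None
    n_nodes: int = 150
    payoff: PayoffRule = field(default_factory=PayoffRule)
    rgrid: RadiusGrid = field(default_factory=RadiusGrid)
    planner_opts: dict = field(
        default_factory=lambda: {"n_starts": 4, "n_nodes": 80, "warm_start": True}
    )

    def __post_init__(self) -> None:
        self._warm_p = None  # last inner-planner solution (ME/MP warm start)
        self._alloc_cache: dict = {}  # planner results keyed by rounded params
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "maximizing_points" and self.experiment != 2:
            raise ValueError("maximizing_points requires the wager experiment (2)")
        t = np.asarray(self.probe_probs, dtype=float)
        if not np.isclose(t.sum(), 1.0):
            raise ValueError("probe probabilities must sum to 1 over probed conditions")

    @property
    def param_names(self) -> list[str]:
        base = {
            "proportional": ["Jbar_total", "tau"],
            "flexible": ["Jbar_total", "tau", "p_high", "p_med"],
            "minimizing_error": ["Jbar_total", "tau", "beta"],
            "maximizing_points": ["Jbar_total", "tau"],
        }[self.strategy]
        if self.experiment == 2:
            base = base + ["lam"]
        return base

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def name(self) -> str:
        return f"exp{self.experiment}:{self.strategy}"

    def get_bounds(self) -> list[tuple[float, float]]:
        over = dict(self.bounds or {})
        return [over.get(p, DEFAULT_BOUNDS[p]) for p in self.param_names]

    def theta_dict(self, theta: Sequence[float]) -> dict[str, float]:
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError(
                f"{self.name} expects {self.n_params} parameters, got {theta.size}"
            )
        return dict(zip(self.param_names, theta.tolist()))

    def allocation(self, theta) -> np.ndarray:
        """Allocation proportions implied by parameters under this strategy."""
        th = theta if isinstance(theta, dict) else self.theta_dict(theta)
        t = np.asarray(self.probe_probs, dtype=float)
        if self.strategy == "proportional":
            return proportional_allocation(t)
        if self.strategy == "flexible":
            return flexible_allocation(th["p_high"], th["p_med"])
        budget = ResourceBudget(th["Jbar_total"], th["tau"])
        po = self.planner_opts
        key = None
        if po.get("warm_start"):
            # cache on ~0.2%-resolution parameters: allocation differences at
            # that scale are far below fit noise
            key = (
                round(np.log10(th["Jbar_total"]), 3),
                round(np.log10(th["tau"]), 3),
                round(th.get("beta", 0.0), 3),
            )
            if key in self._alloc_cache:
                return self._alloc_cache[key]
        starts = None
        if po.get("warm_start") and self._warm_p is not None:
            # continuation: the outer optimizer moves theta slowly, so the
            # previous inner solution is an excellent start; a neutral second
            # start guards against drifting into a local basin
            starts = [self._warm_p, proportional_allocation(t)]
        if self.strategy == "minimizing_error":
            p = minimize_error_allocation(
                budget, th["beta"], t, n_starts=po.get("n_starts", 4), starts=starts
            )
        else:
            p = maximize_points_allocation(
                budget,
                self.payoff,
                t,
                n_starts=po.get("n_starts", 4),
                n_nodes=po.get("n_nodes", 80),
                starts=starts,
            )
        if po.get("warm_start"):
            self._warm_p = p
            self._alloc_cache[key] = p
        return p


def _check_theta(spec: ModelSpec, theta) -> dict[str, float]:
    th = theta if isinstance(theta, dict) else spec.theta_dict(theta)
    for (lo, hi), name in zip(spec.get_bounds(), spec.param_names):
        v = th[name]
        if not (lo <= v <= hi):
            raise ValueError(f"{name}={v:g} outside bounds [{lo:g}, {hi:g}]")
    return th


def _condition_groups(spec: ModelSpec, trials: pd.DataFrame):
    """Yield (probe_prob, allocation index, sub-frame) per priority condition."""
    t = np.asarray(spec.probe_probs, dtype=float)
    order = np.argsort(-t)  # descending priority, matching allocation order
    for rank, idx in enumerate(order):
        sub = trials[np.isclose(trials["priority"], t[idx])]
        yield t[idx], rank, sub


def loglik_exp1(theta, spec: ModelSpec, trials: pd.DataFrame) -> float:
    """Log-likelihood of estimation errors: sum_n log p(eps_n | p_c * Jbar_total, tau).

    The allocation p is fixed by the strategy (Proportional), read from theta
    (Flexible), or computed by the inner planner (ME).  Returns -inf when the
    ME planner's expected loss is infeasible at theta.
    """
    th = _check_theta(spec, theta)
    try:
        p = spec.allocation(th)
    except (DivergentLossError, ValueError):
        return -np.inf
    ll = 0.0
    for _, rank, sub in _condition_groups(spec, trials):
        if len(sub) == 0:
            continue
        d = PrecisionDistribution(p[rank] * th["Jbar_total"], th["tau"])
        grid = precision_grid(d, n_nodes=spec.n_nodes)
        f = rayleigh_error_pdf(sub["error"].to_numpy()[None, :], grid.nodes[:, None])
        dens = grid.weights @ f
        ll += float(np.log(np.maximum(dens, _LOG_FLOOR)).sum())
    return ll


def loglik_exp2(theta, spec: ModelSpec, trials: pd.DataFrame) -> float:
    """Joint log-likelihood of (error, radius) pairs sharing the latent J.

    Per trial: log E_J[f(eps | J) * P(r | J, lam)], with the radius response
    mass a softmax of expected utility over the radius grid.  Observed radii
    off the grid are snapped to the nearest node (with a warning).
    """
    if "radius" not in trials.columns:
        raise ValueError("Exp. 2 likelihood requires a 'radius' column")
    th = _check_theta(spec, theta)
    try:
        p = spec.allocation(th)
    except (DivergentLossError, ValueError):
        return -np.inf
    ll = 0.0
    for _, rank, sub in _condition_groups(spec, trials):
        if len(sub) == 0:
            continue
        d = PrecisionDistribution(p[rank] * th["Jbar_total"], th["tau"])
        grid = precision_grid(d, n_nodes=spec.n_nodes)
        pmat = softmax_radius_matrix(grid.nodes, th["lam"], spec.payoff, spec.rgrid)
        idx = spec.rgrid.snap(sub["radius"].to_numpy())
        f = rayleigh_error_pdf(sub["error"].to_numpy()[None, :], grid.nodes[:, None])
        joint = grid.weights @ (f * pmat[:, idx])
        ll += float(np.log(np.maximum(joint, _LOG_FLOOR)).sum())
    return ll


def log_likelihood(theta, spec: ModelSpec, trials: pd.DataFrame) -> float:
    """Dispatch to the experiment's likelihood."""
    if spec.experiment == 1:
        return loglik_exp1(theta, spec, trials)
    return loglik_exp2(theta, spec, trials)


@dataclass
class FitResult:
    """Outcome of a multistart maximum-likelihood fit."""

    spec_name: str
    param_names: list[str]
    theta_hat: dict[str, float]
    allocation: list[float]
    loglik: float
    aicc: float
    bic: float
    n_trials: int
    n_starts: int
    start_logliks: list[float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls(**json.load(fh))


def information_criteria(loglik: float, n_params: int, n_trials: int):
    """Corrected AIC and BIC.

    ``AICc = -2*LL + 2k + 2k(k+1)/(n-k-1)``; ``BIC = -2*LL + k*ln(n)`` where
    n is the number of analyzed trials for the participant.
    """
    k, n = n_params, n_trials
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    aicc = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    bic = -2.0 * loglik + k * np.log(n)
    return float(aicc), float(bic)


def _lhs_starts(spec: ModelSpec, n_starts: int, rng: np.random.Generator) -> np.ndarray:
    bounds = spec.get_bounds()
    sampler = stats.qmc.LatinHypercube(d=len(bounds), seed=rng)
    u = sampler.random(n_starts)
    starts = np.empty_like(u)
    for j, (name, (lo, hi)) in enumerate(zip(spec.param_names, bounds)):
        if name in _LOG_SCALE:
            starts[:, j] = 10 ** (np.log10(lo) + u[:, j] * (np.log10(hi) - np.log10(lo)))
        else:
            starts[:, j] = lo + u[:, j] * (hi - lo)
    if spec.strategy == "flexible":
        i, j = spec.param_names.index("p_high"), spec.param_names.index("p_med")
        s = starts[:, i] + starts[:, j]
        bad = s > 0.95
        starts[bad, i] *= 0.95 / s[bad]
        starts[bad, j] *= 0.95 / s[bad]
    if spec.strategy == "minimizing_error":
        # pull beta starts inside the finite-expected-loss region
        n_cond = len(spec.probe_probs)
        ib = spec.param_names.index("beta")
        beta_max = 2.0 * 0.8 * starts[:, 0] / (n_cond * starts[:, 1])
        lo_beta = bounds[ib][0]
        starts[:, ib] = np.clip(np.minimum(starts[:, ib], beta_max), lo_beta, None)
    return starts


def _informed_starts(spec: ModelSpec, trials: pd.DataFrame) -> list[np.ndarray]:
    """Method-of-moments starting points from per-condition error medians.

    The Rayleigh median at precision J is sqrt(2 ln 2 / J); ignoring the
    precision spread gives a per-condition precision estimate whose sum
    seeds Jbar_total.  Two tau guesses (strong and weak variability) and,
    for the wager experiment, two decision-noise guesses span the basins.
    """
    Jc = []
    for _, _, sub in _condition_groups(spec, trials):
        med = float(np.median(sub["error"])) if len(sub) else 1.0
        Jc.append(2.0 * np.log(2.0) / max(med, 1e-3) ** 2)
    Jtot = float(np.sum(Jc))
    bounds = dict(zip(spec.param_names, spec.get_bounds()))

    def clipped(name, v):
        lo, hi = bounds[name]
        return float(np.clip(v, lo, hi))

    starts = []
    for tau_frac in (0.15, 0.5):
        th = {
            "Jbar_total": clipped("Jbar_total", Jtot),
            "tau": clipped("tau", tau_frac * Jtot),
        }
        if spec.strategy == "flexible":
            p = np.clip(np.asarray(Jc) / max(Jtot, 1e-9), 0.02, 0.9)
            p = p / p.sum()
            th["p_high"], th["p_med"] = clipped("p_high", p[0]), clipped("p_med", p[1])
        if spec.strategy == "minimizing_error":
            n_cond = len(spec.probe_probs)
            beta_max = 2.0 * 0.8 * th["Jbar_total"] / (n_cond * th["tau"])
            th["beta"] = clipped("beta", min(1.0, beta_max))
        if spec.experiment == 2:
            lams = (2.0, 10.0) if tau_frac == 0.15 else (5.0,)
            for lam in lams:
                starts.append(
                    np.array([{**th, "lam": lam}[n] for n in spec.param_names])
                )
            continue
        starts.append(np.array([th[n] for n in spec.param_names]))
    return starts


def fit_model(
    spec: ModelSpec,
    trials: pd.DataFrame,
    n_starts: int = 10,
    rng_seed: int | np.random.Generator | None = None,
    maxfev_per_dim: int = 400,
) -> FitResult:
    """Multistart bounded Nelder-Mead maximum-likelihood fit.

    Starting points combine a few method-of-moments guesses from the data
    with Latin-hypercube draws within the bounds (log-scale for Jbar_total,
    tau, lam); the best of all runs is returned.  Raises RuntimeError with
    per-start diagnostics if every start fails.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(rng_seed)
    bounds = spec.get_bounds()
    names = spec.param_names
    flex = spec.strategy == "flexible"
    if flex:
        ih, im = names.index("p_high"), names.index("p_med")
    me = spec.strategy == "minimizing_error"
    n_cond = len(spec.probe_probs)

    def negll(x):
        x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
        if flex and x[ih] + x[im] > 0.99:
            return 1e8 * (1.0 + x[ih] + x[im] - 0.99)
        if me:
            # sloped penalty toward the region where the expected loss is
            # finite at some allocation (k_i > beta/2 attainable)
            viol = n_cond * x[2] * x[1] / (2.0 * x[0]) - 0.95
            if viol > 0:
                return 1e6 * (1.0 + viol)
        ll = log_likelihood(x, spec, trials)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    informed = _informed_starts(spec, trials)[:n_starts]
    n_lhs = max(n_starts - len(informed), 0)
    starts = informed + (list(_lhs_starts(spec, n_lhs, rng)) if n_lhs else [])
    results, failures = [], []
    for x0 in starts:
        spec._warm_p = None  # fresh inner-planner state per optimization run
        spec._alloc_cache.clear()
        try:
            res = optimize.minimize(
                negll,
                x0,
                method="Nelder-Mead",
                bounds=bounds,
                options={
                    "xatol": 1e-3,
                    "fatol": 1e-3,
                    "maxfev": maxfev_per_dim * len(names),
                    "adaptive": True,
                },
            )
            results.append(res)
        except Exception as exc:
            failures.append(repr(exc))
    if not results:
        raise RuntimeError(
            "all optimization starts failed:\n" + "\n".join(failures)
        )
    start_lls = [-r.fun for r in results]
    best = results[int(np.argmax(start_lls))]
    theta = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    th = spec.theta_dict(theta)
    spec._warm_p = None  # final allocation and LL from a full planner solve
    spec._alloc_cache.clear()
    ll = log_likelihood(theta, spec, trials)
    aicc, bic = information_criteria(ll, spec.n_params, len(trials))
    return FitResult(
        spec_name=spec.name,
        param_names=names,
        theta_hat=th,
        allocation=[float(v) for v in spec.allocation(th)],
        loglik=float(ll),
        aicc=aicc,
        bic=bic,
        n_trials=len(trials),
        n_starts=len(results),
        start_logliks=[float(v) for v in start_lls],
    )


@dataclass
class ComparisonResult:
    """Paired model comparison over participants.

    ``delta`` values are ``criterion(first) - criterion(second)``: positive
    medians favor the *second* model (lower criterion is better).
    """

    first: str
    second: str
    median_delta_aicc: float
    ci_delta_aicc: tuple[float, float]
    median_delta_bic: float
    ci_delta_bic: tuple[float, float]
    per_participant: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["AICc", "BIC"],
                "comparison": [f"{self.first} - {self.second}"] * 2,
                "median_delta": [self.median_delta_aicc, self.median_delta_bic],
                "ci_lo": [self.ci_delta_aicc[0], self.ci_delta_bic[0]],
                "ci_hi": [self.ci_delta_aicc[1], self.ci_delta_bic[1]],
            }
        )


def _boot_median_ci(x: np.ndarray, n_boot: int, rng: np.random.Generator):
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    meds = np.median(x[idx], axis=1)
    return float(np.percentile(meds, 2.5)), float(np.percentile(meds, 97.5))


def compare_models(
    fits_first: Mapping[object, FitResult],
    fits_second: Mapping[object, FitResult],
    n_boot: int = 10_000,
    rng_seed: int | None = None,
) -> ComparisonResult:
    """Median criterion differences with percentile-bootstrap 95% CIs.

    Both mappings must cover the same participants.  Differences are
    ``first - second`` per participant; the CI resamples participants with
    replacement and takes percentiles of the bootstrap medians.
    """
    if set(fits_first) != set(fits_second):
        raise ValueError("participant sets differ between the two fit collections")
    rng = np.random.default_rng(rng_seed)
    pids = sorted(fits_first)
    rows = []
    for pid in pids:
        a, b = fits_first[pid], fits_second[pid]
        rows.append(
            {
                "participant": pid,
                "delta_aicc": a.aicc - b.aicc,
                "delta_bic": a.bic - b.bic,
            }
        )
    per = pd.DataFrame(rows)
    d_aicc = per["delta_aicc"].to_numpy()
    d_bic = per["delta_bic"].to_numpy()
    return ComparisonResult(
        first=next(iter(fits_first.values())).spec_name,
        second=next(iter(fits_second.values())).spec_name,
        median_delta_aicc=float(np.median(d_aicc)),
        ci_delta_aicc=_boot_median_ci(d_aicc, n_boot, rng),
        median_delta_bic=float(np.median(d_bic)),
        ci_delta_bic=_boot_median_ci(d_bic, n_boot, rng),
        per_participant=per,
    )


def model_recovery(
    specs: Sequence[ModelSpec],
    generating_thetas: Mapping[str, Mapping[str, float]],
    n_datasets: int = 2,
    n_trials: int = 600,
    rng_seed: int | None = None,
    n_starts: int = 5,
    design=None,
) -> pd.DataFrame:
    """AICc model-recovery confusion matrix.

    For each spec (all must share one experiment) simulate ``n_datasets``
    synthetic participants from ``generating_thetas[spec.strategy]``, fit
    every candidate, and record which wins under AICc.  Rows are generating
    models, columns candidate winners; rows sum to 1.
    """
    from vpalloc.simulate import DesignConfig, generate_experiment

    exps = {s.experiment for s in specs}
    if len(exps) != 1:
        raise ValueError("all specs must target the same experiment")
    if design is None:
        design = DesignConfig(n_trials=n_trials)
    ss = np.random.SeedSequence(rng_seed)
    names = [s.strategy for s in specs]
    confusion = pd.DataFrame(0.0, index=names, columns=names)
    for gen in specs:
        theta = dict(generating_thetas[gen.strategy])
        for _ in range(n_datasets):
            sim_seed, fit_seed = ss.spawn(2)
            trials = generate_experiment(
                gen, theta, design, rng_seed=sim_seed.generate_state(1)[0] % 2**31
            )
            aiccs = {}
            for cand in specs:
                fit = fit_model(
                    cand,
                    trials,
                    n_starts=n_starts,
                    rng_seed=np.random.default_rng(fit_seed.spawn(1)[0]),
                )
                aiccs[cand.strategy] = fit.aicc
            winner = min(aiccs, key=aiccs.get)
            confusion.loc[gen.strategy, winner] += 1.0
    return confusion.div(confusion.sum(axis=1), axis=0)
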