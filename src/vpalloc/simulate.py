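"""Synthetic experiment generator faithful to the memory-guided saccade task.

Each trial shows four dots, one per visual quadrant, with probe
probabilities 0.6 / 0.3 / 0.1 / 0.0 assigned to the quadrants.  Targets sit
at ~10 dva eccentricity (1 dva radial jitter) on a 10-degree polar-angle
grid that avoids the cardinal axes.  After a delay of 1000-4000 ms (500 ms
steps) one quadrant is probed and the observer saccades to the remembered
location; in the wager experiment a confidence circle follows.  Only the
probed item is recorded, matching the analyzed human data (one analyzed
response per trial, post exclusion screening).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from vpalloc.wager import PayoffRule, RadiusGrid, expected_utility, points

__all__ = [
    "DesignConfig",
    "TRIAL_COLUMNS",
    "generate_targets",
    "generate_experiment",
    "write_trials",
    "read_trials",
]

#: Column schema (v1) of a trial table.  'radius', 'points_earned' are wager-
#: experiment only; 'J' is the latent precision, stored for testing only.
TRIAL_COLUMNS = {
    "participant": "participant id (int or str)",
    "trial": "trial index within participant",
    "priority": "probe probability of the probed item (0.6 / 0.3 / 0.1)",
    "target_x": "true target x (dva)",
    "target_y": "true target y (dva)",
    "response_x": "saccade endpoint x (dva)",
    "response_y": "saccade endpoint y (dva)",
    "error": "Euclidean estimation error (dva)",
    "delay_ms": "memory delay (ms), 1000-4000 in 500 ms steps",
    "radius": "wager circle radius (dva; wager experiment only)",
    "points_earned": "points from the wager (0 on a miss)",
    "J": "latent precision (dva^-2; synthetic data only)",
}

_REQUIRED = [
    "participant",
    "trial",
    "priority",
    "target_x",
    "target_y",
    "response_x",
    "response_y",
    "error",
    "delay_ms",
]


@dataclass(frozen=True)
class DesignConfig:
    """Task-design constants and synthetic-sample sizes.

    Defaults reproduce the published design: probe probabilities
    (0.6, 0.3, 0.1) over the probed conditions (the 0.0 quadrant is never
    probed and gets no resource), targets at 10 +/- 1 dva on a 10-degree
    angular grid avoiding cardinals, delays 1000-4000 ms by 500.
    ``n_trials = 600`` per synthetic participant is an assumption (per-session
    counts are not published).  ``dropout`` optionally discards a uniform
    random fraction of trials, emulating the 1-7% screening exclusions;
    ``delay_decay`` (1/s) optionally scales mean precision by
    ``exp(-delay_decay * delay_s)`` — off by default, a hook for exercising
    the delay-confound permutation test.
    """

    probe_probs: tuple[float, ...] = (0.6, 0.3, 0.1)
    n_trials: int = 600
    eccentricity: float = 10.0
    jitter: float = 1.0
    angle_step_deg: float = 10.0
    delays_ms: tuple[int, ...] = (1000, 1500, 2000, 2500, 3000, 3500, 4000)
    payoff: PayoffRule = field(default_factory=PayoffRule)
    rgrid: RadiusGrid = field(default_factory=RadiusGrid)
    dropout: float = 0.0
    delay_decay: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.probe_probs)
        if not np.isclose(t.sum(), 1.0):
            raise ValueError("probe probabilities must sum to 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def angle_grid_deg(self) -> np.ndarray:
        """Polar angles of the target grid: multiples of the step, no cardinals."""
        angles = np.arange(self.angle_step_deg, 360.0, self.angle_step_deg)
        return angles[~np.isclose(angles % 90.0, 0.0)]


def generate_targets(
    design: DesignConfig, n: int, rng_seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Sample target locations, one per visual quadrant per trial.

    Returns an (n, 4, 2) array of xy positions (dva); quadrant q (0-3) covers
    polar angles (90q, 90q+90).  Angles come from the design's 10-degree grid
    (cardinals excluded); eccentricity jitter is radial, uniform within
    +/- ``design.jitter`` dva, so grid angles are preserved exactly.
    """
    rng = np.random.default_rng(rng_seed)
    grid = design.angle_grid_deg
    out = np.empty((n, 4, 2))
    for q in range(4):
        in_q = grid[(grid > 90 * q) & (grid < 90 * (q + 1))]
        ang = np.deg2rad(rng.choice(in_q, size=n))
        ecc = design.eccentricity + rng.uniform(-design.jitter, design.jitter, size=n)
        out[:, q, 0] = ecc * np.cos(ang)
        out[:, q, 1] = ecc * np.sin(ang)
    return out


def generate_experiment(
    spec,
    theta,
    design: DesignConfig | None = None,
    rng_seed: int | np.random.Generator | None = None,
    participant: object = 0,
    keep_latent: bool = False,
) -> pd.DataFrame:
    """Simulate one synthetic participant from a model spec and parameters.

    Per trial: priorities are assigned to quadrants at random; the probed
    condition is drawn with the probe probabilities; the latent precision J
    comes from the condition's gamma (mean ``p_c * Jbar_total``, scale tau);
    the saccade endpoint is the target plus an isotropic Gaussian deviation
    with per-axis sd ``J**-0.5``.  For the wager experiment the circle radius
    is drawn from the softmax-of-expected-utility mass and points are scored
    with the hit indicator.  Identical seeds give identical tables.
    """
    if design is None:
        design = DesignConfig()
    rng = np.random.default_rng(rng_seed)
    th = theta if isinstance(theta, dict) else spec.theta_dict(theta)
    p = spec.allocation(th)
    t = np.asarray(design.probe_probs, dtype=float)
    order = np.argsort(-t)
    n = design.n_trials

    cond_idx = rng.choice(len(t), size=n, p=t)  # index into probe_probs
    rank = np.empty(len(t), dtype=int)  # condition -> allocation slot
    rank[order] = np.arange(len(t))
    targets = generate_targets(design, n, rng)
    # priorities are shuffled over quadrants each trial; record the probed one
    probed_quadrant = rng.integers(0, 4, size=n)
    tx = targets[np.arange(n), probed_quadrant, 0]
    ty = targets[np.arange(n), probed_quadrant, 1]
    delay = rng.choice(design.delays_ms, size=n)

    Jbar_c = p[rank[cond_idx]] * th["Jbar_total"]
    if design.delay_decay > 0:
        Jbar_c = Jbar_c * np.exp(-design.delay_decay * delay / 1000.0)
    # floor keeps the arithmetic defined when extreme gamma shapes underflow
    # to 0.0 (reachable only at degenerate allocations); sd at the floor is
    # ~1e6 dva, i.e. "no memory at all"
    J = np.maximum(rng.gamma(shape=Jbar_c / th["tau"], scale=th["tau"]), 1e-12)
    offsets = rng.standard_normal((n, 2)) / np.sqrt(J)[:, None]
    rx, ry = tx + offsets[:, 0], ty + offsets[:, 1]
    err = np.hypot(offsets[:, 0], offsets[:, 1])

    df = pd.DataFrame(
        {
            "participant": participant,
            "trial": np.arange(n),
            "priority": t[cond_idx],
            "target_x": tx,
            "target_y": ty,
            "response_x": rx,
            "response_y": ry,
            "error": err,
            "delay_ms": delay,
        }
    )
    if spec.experiment == 2:
        lam = th["lam"]
        rvals = design.rgrid.values
        eu = expected_utility(rvals[None, :], J[:, None], design.payoff)
        eu = eu - eu.max(axis=1, keepdims=True)
        w = np.exp(eu / lam)
        cdf = np.cumsum(w, axis=1)
        cdf /= cdf[:, -1:]
        u = rng.uniform(size=(n, 1))
        choice = (u > cdf).sum(axis=1)
        radius = rvals[choice]
        hit = err <= radius
        df["radius"] = radius
        df["points_earned"] = np.where(hit, points(radius, design.payoff), 0.0)
    if keep_latent:
        df["J"] = J
    if design.dropout > 0:
        keep = rng.uniform(size=n) >= design.dropout
        df = df[keep].reset_index(drop=True)
    return df


def write_trials(trials: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a trial table to CSV (lossless float round trip).

    ``meta`` (e.g. the design and generating parameters) goes to a JSON
    sidecar at ``<path>.meta.json``.
    """
    trials.to_csv(path, index=False)
    if meta is not None:
        clean = {}
        for k, v in meta.items():
            if isinstance(v, (DesignConfig, PayoffRule, RadiusGrid)):
                v = {
                    kk: vv
                    for kk, vv in asdict(v).items()
                    if not isinstance(vv, np.ndarray)
                }
            clean[k] = v
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(clean, fh, indent=2, default=str)


def read_trials(path, validate: bool = True) -> pd.DataFrame:
    """Read and schema-validate a trial table written by :func:`write_trials`.

    Validation checks required columns, the priority and delay vocabularies,
    and the consistency of the stored error with the coordinates (1e-9 dva);
    violations raise ValueError naming the column and first offending row.
    """
    df = pd.read_csv(path)
    if not validate:
        return df
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    recomputed = np.hypot(
        df["target_x"] - df["response_x"], df["target_y"] - df["response_y"]
    )
    bad = np.abs(recomputed - df["error"]) > 1e-9
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ValueError(
            f"column 'error' inconsistent with coordinates at row {row}: "
            f"stored {df['error'].iloc[row]:.9f}, recomputed {recomputed.iloc[row]:.9f}"
        )
    allowed_delays = set(range(1000, 4001, 500))
    bad_delay = ~df["delay_ms"].isin(allowed_delays)
    if bad_delay.any():
        row = int(np.argmax(bad_delay.to_numpy()))
        raise ValueError(f"column 'delay_ms' invalid at row {row}: {df['delay_ms'].iloc[row]}")
    bad_pri = ~((df["priority"] > 0) & (df["priority"] <= 1))
    if bad_pri.any():
        row = int(np.argmax(bad_pri.to_numpy()))
        raise ValueError(f"column 'priority' invalid at row {row}: {df['priority'].iloc[row]}")
    return df
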