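"""Independent oracles used only by the test suite.

These deliberately avoid the package's computational path: the marginal
error density has a hand-derived closed form (integrating the Rayleigh
against the gamma gives a Burr-type density), expectations are checked by
Monte Carlo, and simplex optima by brute-force grid search.
"""

import numpy as np
from scipy.special import gammaln


def closed_form_marginal_pdf(eps, Jbar, tau):
    """Closed form of E_J[J eps exp(-J eps^2/2)] with J ~ Gamma(Jbar/tau, tau).

    Integrating the Rayleigh kernel against the gamma density gives
    eps * k / (tau**k * (eps**2/2 + 1/tau)**(k+1)), k = Jbar/tau
    (evaluated in logs for numerical range).
    """
    eps = np.asarray(eps, dtype=float)
    k = Jbar / tau
    with np.errstate(divide="ignore"):
        log_val = (
            np.log(k)
            + np.log(eps)
            - k * np.log(tau)
            - (k + 1) * np.log(eps**2 / 2 + 1 / tau)
        )
    return np.exp(log_val)


def mc_expected_error_power(Jbar, tau, beta, n=1_000_000, seed=0):
    """Monte-Carlo E[eps**beta]: sample J, then a 2-D Gaussian deviation."""
    rng = np.random.default_rng(seed)
    J = rng.gamma(Jbar / tau, scale=tau, size=n)
    xy = rng.standard_normal((n, 2)) / np.sqrt(J)[:, None]
    eps_b = np.hypot(xy[:, 0], xy[:, 1]) ** beta
    est = eps_b.mean()
    se = eps_b.std(ddof=1) / np.sqrt(n)
    return est, se


def mean_error_closed_form(Jbar, tau):
    """E[eps] = sqrt(pi/2) * E[J**-0.5]; needs k = Jbar/tau > 1/2."""
    k = Jbar / tau
    if k <= 0.5:
        raise ValueError("mean error diverges for k <= 1/2")
    return np.sqrt(np.pi / 2) * np.exp(gammaln(k - 0.5) - gammaln(k)) / np.sqrt(tau)


def simplex_grid(step, floor=1e-3):
    """All 3-simplex points on a regular grid with every entry >= floor."""
    vals = np.arange(floor, 1.0, step)
    pts = []
    for p1 in vals:
        for p2 in vals:
            p3 = 1.0 - p1 - p2
            if p3 >= floor:
                pts.append((p1, p2, p3))
    return np.array(pts)


def brute_force_me(step, Jbar_total, tau, beta, t, floor=1e-3):
    """Grid minimum of the probe-weighted expected error power (vectorized)."""
    pts = simplex_grid(step, floor)
    k = pts * Jbar_total / tau  # (n_pts, 3)
    obj = np.full(len(pts), np.inf)
    ok = np.all(k > beta / 2, axis=1)
    if ok.any():
        const = (beta / 2) * np.log(2) + gammaln(1 + beta / 2) - (beta / 2) * np.log(tau)
        e_pow = np.exp(const + gammaln(k[ok] - beta / 2) - gammaln(k[ok]))
        obj[ok] = e_pow @ np.asarray(t)
    i = int(np.argmin(obj))
    return pts[i], obj[i]


def brute_force_mp(step, Jbar_total, tau, t, mp_gain, floor=1e-3):
    """Grid maximum of the expected-points objective.

    ``mp_gain(k)`` maps a vector of gamma shapes to per-condition expected
    optimal-wager values; supplied by the test, typically an interpolant of
    the package-independent definition evaluated on a dense shape grid.
    """
    pts = simplex_grid(step, floor)
    k = pts * Jbar_total / tau
    gains = mp_gain(k)  # (n_pts, 3)
    obj = gains @ np.asarray(t)
    i = int(np.argmax(obj))
    return pts[i], obj[i]
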