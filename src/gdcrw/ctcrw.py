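"""Exact continuous-time correlated random walk (integrated Ornstein-Uhlenbeck).

With rotation zero and a diagonal noise loading, the two coordinates decouple
and each follows the classic continuous-time correlated random walk: velocity
``dv = -beta (v - mu) dt + sigma dB`` with ``beta = -log(gamma)``, location
``dx = v dt``.  The (position, velocity) pair is linear-Gaussian with the
closed-form transition

    T(D) = [[1, (1 - e^{-bD}) / b], [0, e^{-bD}]]

and process covariance with entries

    q_xx = s^2/b^2 (D - 2(1 - e^{-bD})/b + (1 - e^{-2bD})/(2b))
    q_xv = s^2/(2 b^2) (1 - e^{-bD})^2
    q_vv = s^2 (1 - e^{-2bD}) / (2b)

which reduce to the integrated-Brownian-motion forms ``s^2 D^3/3``,
``s^2 D^2/2``, ``s^2 D`` as ``b -> 0`` (handled by series expansion).  The
likelihood is the exact Kalman marginal; no time discretization is involved.
"""

from __future__ import annotations

import numpy as np

from ._kalman import filter2, smooth2
from .data import ObservationSet

__all__ = ["ctcrw_system", "ctcrw_loglik", "ctcrw_smooth"]

_DIFFUSE_SD = 1e4


def ctcrw_step(beta: float, sigma: float, deltas: np.ndarray):
    """Per-step transition matrices and covariances for one coordinate."""
    d = np.asarray(deltas, dtype=float)
    s2 = sigma * sigma
    u = beta * d
    # the closed forms cancel catastrophically for small beta*D; switch to
    # series whose truncation error (~u^4) is below 1e-8 at the threshold
    small = u < 1e-2
    u2, u3 = u * u, u * u * u
    with np.errstate(divide="ignore", invalid="ignore"):
        em = np.exp(-u)
        em2 = np.exp(-2 * u)
        t_xv = np.where(small, d * (1 - u / 2 + u2 / 6 - u3 / 24), (1 - em) / beta)
        q_vv = np.where(
            small,
            s2 * d * (1 - u + 2 * u2 / 3 - u3 / 3),
            s2 * (1 - em2) / (2 * beta),
        )
        q_xv = np.where(
            small,
            s2 * d * d / 2 * (1 - u + 7 * u2 / 12 - u3 / 4),
            s2 * (1 - em) ** 2 / (2 * beta * beta),
        )
        q_xx = np.where(
            small,
            s2 * d**3 * (1.0 / 3 - u / 4 + 7 * u2 / 60 - u3 / 24),
            s2 / beta**2 * (d - 2 * (1 - em) / beta + (1 - em2) / (2 * beta)),
        )
    n = d.shape[0]
    T = np.zeros((n, 2, 2))
    T[:, 0, 0] = 1.0
    T[:, 0, 1] = t_xv
    T[:, 1, 1] = em
    Q = np.empty((n, 2, 2))
    Q[:, 0, 0] = q_xx
    Q[:, 0, 1] = Q[:, 1, 0] = q_xv
    Q[:, 1, 1] = q_vv
    return T, Q


def ctcrw_system(
    beta: float, sigma: float, obs_times: np.ndarray, mu: float = 0.0
):
    """Assemble the per-coordinate system on the (deduplicated) observation times."""
    t = np.asarray(obs_times, dtype=float)
    # collapse duplicate times to shared states
    keep = np.concatenate([[True], np.diff(t) > 1e-9])
    grid = t[keep]
    state = np.cumsum(keep) - 1
    deltas = np.diff(grid)
    T, Q = ctcrw_step(beta, sigma, deltas)
    c = np.zeros((deltas.shape[0], 2))
    if mu != 0.0:
        c[:, 0] = mu * (deltas - T[:, 0, 1])
        c[:, 1] = mu * (1.0 - T[:, 1, 1])
    return grid, state, T, c, Q


def _init(beta: float, sigma: float, mu: float, y0: float):
    a0 = np.array([y0, mu])
    P0 = np.diag([_DIFFUSE_SD**2, sigma * sigma / (2 * beta)])
    return a0, P0


def ctcrw_loglik(
    gamma: float, sigma: float, obs: ObservationSet, obs_var: float, mu=(0.0, 0.0)
) -> float:
    """Exact marginal log-likelihood, summed over the two coordinates."""
    beta = -np.log(gamma)
    if beta <= 0:
        raise ValueError("gamma must be in (0, 1) for the exact transition")
    ll = 0.0
    for coord in range(2):
        grid, state, T, c, Q = ctcrw_system(beta, sigma, obs.times, mu[coord])
        y = np.ascontiguousarray(obs.coords[:, coord])
        a0, P0 = _init(beta, sigma, mu[coord], y[0])
        h_var = np.full(y.shape[0], obs_var)
        l, ok, *_ = filter2(a0, P0, T, c, Q, state, h_var, y, grid.shape[0], False)
        if not ok:
            return -np.inf
        ll += l
    return ll


def ctcrw_smooth(
    gamma: float, sigma: float, obs: ObservationSet, obs_var: float, mu=(0.0, 0.0)
):
    """Smoothed locations and marginal location variances at the state times.

    Returns ``(times, locations (n,2), location variances (n,2))``.
    """
    beta = -np.log(gamma)
    locs = []
    vars_ = []
    grid = None
    for coord in range(2):
        grid, state, T, c, Q = ctcrw_system(beta, sigma, obs.times, mu[coord])
        y = np.ascontiguousarray(obs.coords[:, coord])
        a0, P0 = _init(beta, sigma, mu[coord], y[0])
        h_var = np.full(y.shape[0], obs_var)
        _, ok, pa, pP, fa, fP = filter2(
            a0, P0, T, c, Q, state, h_var, y, grid.shape[0], True
        )
        if not ok:
            raise FloatingPointError("Kalman filter failed")
        sa, sP = smooth2(T, pa, pP, fa, fP)
        locs.append(sa[:, 0])
        vars_.append(sP[:, 0, 0])
    return grid, np.column_stack(locs), np.column_stack(vars_)
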