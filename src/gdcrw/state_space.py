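"""Discrete-time state-space assembly on an estimation time grid.

The movement model is discretized on a set of estimation time points
``t_1 < ... < t_N`` (a :class:`TimeGrid`).  Writing ``D_i = t_i - t_{i-1}``
and ``A_i = exp(-Theta D_i)``, consecutive locations follow the
irregular-step first-difference transition

    X_i = X_{i-1} + D_i A_{i-1} (X_{i-1} - X_{i-2}) / D_{i-1}
          + D_i (I - A_{i-1}) mu + D_i eps_i,

with ``Var(eps_i) = C - A C A^T`` (``C`` the stationary velocity
covariance).  By default the variance uses ``A = A_{i-1}``, matching the
derivation of ``eps_i`` as the velocity innovation over the gap ending at
``t_{i-1}``; the alternative ``A = A_i`` convention is available as a
switch.  Stacking ``alpha_i = (X_i, X_{i-1})`` gives a linear-Gaussian
state-space model; observations load either directly on an aligned grid
point or on a convex combination of the two bracketing points (linear
interpolation), depending on the grid scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ObservationSet
from .kinematics import propagator_many, stationary_velocity_cov
from .params import MovementParams

__all__ = [
    "TimeGrid",
    "StateSystem",
    "build_grid_aligned",
    "build_grid_regular",
    "interpolation_weights",
    "assemble_system",
]

#: Two grid times closer than this are collapsed to one point.
DEDUP_TOL = 1e-9

#: Auxiliary points inserted by spacing are dropped when this close to an
#: existing grid point, to avoid near-degenerate time steps.
MIN_AUX_GAP = 1e-2

#: Standard deviation of the diffuse prior on the first latent location.
DIFFUSE_SD = 1e4


@dataclass(frozen=True)
class TimeGrid:
    """Ordered estimation time points with observation-alignment flags."""

    times: np.ndarray
    aligned: np.ndarray  # bool, True where the point coincides with an observation

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.aligned, dtype=bool)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times and aligned must be 1-d arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("grid times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "aligned", a)

    def __len__(self) -> int:
        return self.times.shape[0]

    @property
    def deltas(self) -> np.ndarray:
        """Step lengths ``D_i = t_i - t_{i-1}`` (length N-1)."""
        return np.diff(self.times)


def build_grid_aligned(
    obs_times: np.ndarray,
    extra_spacing: float | None = None,
    extra_total: int | None = None,
) -> TimeGrid:
    """Grid containing every observation time, plus optional auxiliary points.

    With ``extra_spacing=k`` auxiliary points are placed every ``k`` time
    units from the first observation (deduplicated against, and kept clear
    of, observation times).  With ``extra_total=M``, ``M`` auxiliary points
    are inserted one at a time at the midpoint of the currently longest
    inter-grid gap (ties broken toward the earliest gap).  Auxiliary points
    refine the time discretization without contributing observations.
    """
    if extra_spacing is not None and extra_total is not None:
        raise ValueError("give at most one of extra_spacing / extra_total")
    obs_times = np.asarray(obs_times, dtype=float)
    if np.any(np.diff(obs_times) < 0):
        raise ValueError("obs_times must be sorted")
    # collapse duplicate observation times to single grid points
    base = [obs_times[0]]
    for t in obs_times[1:]:
        if t - base[-1] > DEDUP_TOL:
            base.append(t)
    base = np.asarray(base)

    if extra_spacing is not None:
        if extra_spacing <= 0:
            raise ValueError("extra_spacing must be positive")
        aux = np.arange(base[0] + extra_spacing, base[-1], extra_spacing)
        keep = np.abs(aux[:, None] - base[None, :]).min(axis=1) > MIN_AUX_GAP
        aux = aux[keep]
    elif extra_total is not None:
        if extra_total < 0:
            raise ValueError("extra_total must be nonnegative")
        pts = list(base)
        for _ in range(extra_total):
            gaps = np.diff(pts)
            j = int(np.argmax(gaps))  # argmax takes the earliest maximum
            pts.insert(j + 1, pts[j] + 0.5 * gaps[j])
        aux = np.setdiff1d(np.asarray(pts), base)
    else:
        aux = np.empty(0)

    times = np.concatenate([base, aux])
    aligned = np.concatenate([np.ones(base.size, bool), np.zeros(aux.size, bool)])
    order = np.argsort(times, kind="stable")
    return TimeGrid(times[order], aligned[order])


def build_grid_regular(obs_times: np.ndarray, n_points: int) -> TimeGrid:
    """``n_points`` equally spaced grid times spanning the observation window."""
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    obs_times = np.asarray(obs_times, dtype=float)
    times = np.linspace(obs_times[0], obs_times[-1], n_points)
    aligned = np.zeros(n_points, bool)
    aligned[0] = aligned[-1] = True
    return TimeGrid(times, aligned)


def interpolation_weights(
    obs_times: np.ndarray, grid: TimeGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Bracketing interval and linear weight for each observation time.

    Returns ``(interval, q)`` with ``t[i] <= s < t[i+1]`` for
    ``i = interval`` (0-based) and ``q = (s - t[i]) / (t[i+1] - t[i])`` so
    that ``Y = (1-q) X_i + q X_{i+1} + eta``.  An observation at exactly the
    last grid time gets the last interval with ``q = 1``.
    """
    s = np.asarray(obs_times, dtype=float)
    t = grid.times
    if np.any(s < t[0] - DEDUP_TOL) or np.any(s > t[-1] + DEDUP_TOL):
        raise ValueError("observation outside the grid span")
    s = np.clip(s, t[0], t[-1])
    idx = np.searchsorted(t, s, side="right") - 1
    idx = np.clip(idx, 0, len(t) - 2)
    q = (s - t[idx]) / (t[idx + 1] - t[idx])
    return idx, q


@dataclass
class StateSystem:
    """Linear-Gaussian system on paired-location states ``alpha_i = (X_i, X_{i-1})``.

    States are indexed ``k = 0..N-2`` for grid indices ``i = 2..N``.  ``T``,
    ``c`` and ``Q`` (each length N-2) map state ``k-1`` to state ``k``; the
    initial state has mean ``a0`` and covariance ``P0``.  Observations are
    sorted by state: observation ``j`` loads on state ``obs_state[j]`` through
    the 2x4 matrix ``H[j]`` with error covariance ``R[j]`` (Gaussian case) or
    the per-record t specification carried alongside.
    """

    grid: TimeGrid
    mode: str
    a0: np.ndarray
    P0: np.ndarray
    T: np.ndarray
    c: np.ndarray
    Q: np.ndarray
    obs_state: np.ndarray
    H: np.ndarray
    y: np.ndarray
    R: np.ndarray
    obs_order: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_states(self) -> int:
        return len(self.grid) - 1


def _observation_operators(
    grid: TimeGrid, obs: ObservationSet, mode: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map each observation to (state index, 2x4 loading matrix)."""
    n_obs = len(obs)
    H = np.zeros((n_obs, 2, 4))
    state = np.empty(n_obs, dtype=np.int64)
    t = grid.times
    if mode == "aligned":
        idx = np.searchsorted(t, obs.times)
        idx = np.clip(idx, 0, len(t) - 1)
        near = np.where(
            np.abs(t[idx] - obs.times)
            <= np.abs(t[np.maximum(idx - 1, 0)] - obs.times),
            idx,
            np.maximum(idx - 1, 0),
        )
        if np.any(np.abs(t[near] - obs.times) > DEDUP_TOL):
            raise ValueError("aligned mode requires every observation time in the grid")
        for j, i in enumerate(near):
            if i == 0:
                # first grid point lives in the second block of state 0
                state[j] = 0
                H[j, 0, 2] = H[j, 1, 3] = 1.0
            else:
                state[j] = i - 1
                H[j, 0, 0] = H[j, 1, 1] = 1.0
    elif mode == "interpolated":
        interval, q = interpolation_weights(obs.times, grid)
        for j in range(n_obs):
            i, qq = interval[j], q[j]
            # state k = i holds alpha_{i+2} = (X_{i+1}, X_i) in 0-based grid terms
            state[j] = i
            H[j, 0, 0] = H[j, 1, 1] = qq
            H[j, 0, 2] = H[j, 1, 3] = 1.0 - qq
    else:
        raise ValueError(f"unknown mode {mode!r}")
    order = np.argsort(state, kind="stable")
    return state[order], H[order], order


def _transition_system(
    params: MovementParams,
    deltas: np.ndarray,
    y1: np.ndarray,
    use_prev_delta_in_var: bool = True,
):
    """Vectorized transition matrices, offsets, covariances and initial state."""
    C = stationary_velocity_cov(params)
    I2 = np.eye(2)
    n_tr = deltas.shape[0] - 1
    constant_step = n_tr > 0 and np.ptp(deltas) <= 1e-12 * deltas[0]
    if constant_step:
        # regular grid: one transition repeated (cheap inside optimizers)
        d = deltas[0]
        A1 = propagator_many(params, np.array([d]))[0]
        var_eps = C - A1 @ C @ A1.T
        var_eps = 0.5 * (var_eps + var_eps.T)
        T1 = np.zeros((4, 4))
        T1[:2, :2] = I2 + A1
        T1[:2, 2:] = -A1
        T1[2:, :2] = I2
        c1 = np.zeros(4)
        c1[:2] = d * ((I2 - A1) @ params.mu)
        Q1 = np.zeros((4, 4))
        Q1[:2, :2] = d * d * var_eps
        T = np.broadcast_to(T1, (n_tr, 4, 4)).copy()
        c = np.broadcast_to(c1, (n_tr, 4)).copy()
        Q = np.broadcast_to(Q1, (n_tr, 4, 4)).copy()
    else:
        A = propagator_many(params, deltas)  # A[k] = exp(-Theta * deltas[k])
        ACA = A @ C @ np.transpose(A, (0, 2, 1))
        d_prev = deltas[:-1]  # D_{i-1}
        d_cur = deltas[1:]  # D_i
        r = (d_cur / d_prev)[:, None, None]
        Aprev = A[:-1]
        T = np.zeros((n_tr, 4, 4))
        T[:, :2, :2] = I2 + r * Aprev
        T[:, :2, 2:] = -r * Aprev
        T[:, 2:, :2] = I2
        c = np.zeros((n_tr, 4))
        c[:, :2] = d_cur[:, None] * ((I2 - Aprev) @ params.mu)
        var_eps = C - (ACA[:-1] if use_prev_delta_in_var else ACA[1:])
        var_eps = 0.5 * (var_eps + np.transpose(var_eps, (0, 2, 1)))
        Q = np.zeros((n_tr, 4, 4))
        Q[:, :2, :2] = (d_cur * d_cur)[:, None, None] * var_eps

    # Initial state alpha_2 = (X_2, X_1): X_1 diffuse around the first
    # observation; X_2 = X_1 + D_2 V_1 with V_1 ~ N(mu, C) at stationarity.
    d2 = deltas[0]
    tau2 = DIFFUSE_SD**2
    a0 = np.concatenate([y1 + d2 * params.mu, y1])
    P0 = np.full((4, 4), tau2) * np.kron(np.ones((2, 2)), I2)
    P0[:2, :2] += d2 * d2 * C
    return a0, P0, T, c, Q


def assemble_system(
    params: MovementParams,
    grid: TimeGrid,
    obs: ObservationSet,
    mode: str = "aligned",
    noise_cov: np.ndarray | None = None,
    use_prev_delta_in_var: bool = True,
) -> StateSystem:
    """Build the transition and observation system for the given parameters.

    ``noise_cov`` may be a single 2x2 Gaussian covariance (shared) or an
    (n_obs, 2, 2) array; it defaults to ``0.1^2 I``.  By default the process
    noise variance uses the previous gap ``D_{i-1}``, consistent with the
    propagator (the velocity innovation is realized over the gap ending at
    ``t_{i-1}``); ``use_prev_delta_in_var=False`` selects the alternative
    current-gap ``D_i`` convention.  The two coincide on regular grids.
    """
    N = len(grid)
    if N < 2:
        raise ValueError("grid must have at least two points")
    y1 = obs.coords[0] if len(obs) else np.zeros(2)
    a0, P0, T, c, Q = _transition_system(
        params, grid.deltas, y1, use_prev_delta_in_var
    )
    obs_state, H, order = _observation_operators(grid, obs, mode)
    if noise_cov is None:
        noise_cov = 0.1**2 * np.eye(2)
    noise_cov = np.asarray(noise_cov, dtype=float)
    if noise_cov.shape == (2, 2):
        R = np.broadcast_to(noise_cov, (len(obs), 2, 2)).copy()
    else:
        R = noise_cov[order].copy()
    y = obs.coords[order]
    return StateSystem(grid, mode, a0, P0, T, c, Q, obs_state, H, y, R, order)
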