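"""Continuous-time track simulation.

Tracks are simulated from the velocity/location stochastic differential
equation by the Euler-Maruyama scheme on a fine grid: between consecutive
observation times a fixed number of additional points (200 by default) are
inserted so the simulated path emulates continuous-time movement.
Observation times themselves are drawn irregularly, with increments from a
truncated exponential/normal mixture, and measurements are the true location
plus Gaussian or Student-t error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .data import ObservationSet, TruePath
from .kinematics import increment_velocity_cov, propagator, stationary_velocity_cov
from .noise import NoiseModel
from .params import MovementParams

__all__ = [
    "StepMixtureConfig",
    "sample_observation_times",
    "simulate_continuous",
    "simulate_observations",
]


@dataclass(frozen=True)
class StepMixtureConfig:
    """Distribution of time gaps between observations.

    A two-component mixture: with probability ``weight_exp`` an
    ``Exponential(rate)`` draw (many short gaps), otherwise a
    ``Normal(normal_mean, normal_sd)`` draw (a cluster of long gaps).  Draws
    are truncated below at ``floor`` so gaps stay strictly positive.  The
    defaults give a mixture mean of about 2 time units, mimicking telemetry
    with both bursts and long surfacing gaps.
    """

    weight_exp: float = 0.5
    rate: float = 1.0
    normal_mean: float = 3.0
    normal_sd: float = 0.5
    floor: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_exp <= 1.0:
            raise ValueError("weight_exp must be in [0, 1]")
        if self.rate <= 0 or self.normal_sd <= 0 or self.floor <= 0:
            raise ValueError("rate, normal_sd and floor must be positive")

    @property
    def mean(self) -> float:
        """Mixture mean ignoring the (tiny) truncation correction."""
        return self.weight_exp / self.rate + (1 - self.weight_exp) * self.normal_mean


def sample_observation_times(
    n: int, cfg: StepMixtureConfig | None = None, seed=None
) -> np.ndarray:
    """Draw ``n`` strictly increasing observation times starting at 0."""
    if n < 2:
        raise ValueError("need at least two observation times")
    cfg = cfg or StepMixtureConfig()
    rng = np.random.default_rng(seed)
    comp = rng.random(n - 1) < cfg.weight_exp
    gaps = np.where(
        comp,
        rng.exponential(1.0 / cfg.rate, n - 1),
        rng.normal(cfg.normal_mean, cfg.normal_sd, n - 1),
    )
    gaps = np.maximum(gaps, cfg.floor)
    return np.concatenate([[0.0], np.cumsum(gaps)])


@njit(cache=True)
def _euler_core(times, v0, x0, Th, S, Z):  # pragma: no cover - jit
    n = times.shape[0]
    X = np.empty((n, 2))
    V = np.empty((n, 2))
    X[0] = x0
    V[0] = v0
    for k in range(n - 1):
        d = times[k + 1] - times[k]
        sq = np.sqrt(d)
        # dV = -Theta (V - mu) dt + S sqrt(dt) Z ; mu folded into Th drift b
        V[k + 1, 0] = (
            V[k, 0]
            - (Th[0, 0] * V[k, 0] + Th[0, 1] * V[k, 1] - Th[0, 2]) * d
            + (S[0, 0] * Z[k, 0]) * sq
        )
        V[k + 1, 1] = (
            V[k, 1]
            - (Th[1, 0] * V[k, 0] + Th[1, 1] * V[k, 1] - Th[1, 2]) * d
            + (S[1, 0] * Z[k, 0] + S[1, 1] * Z[k, 1]) * sq
        )
        X[k + 1, 0] = X[k, 0] + V[k, 0] * d
        X[k + 1, 1] = X[k, 1] + V[k, 1] * d
    return X, V


def _fine_grid(obs_times: np.ndarray, substeps: int) -> tuple[np.ndarray, np.ndarray]:
    n = obs_times.shape[0]
    m = substeps + 1
    fine = np.empty((n - 1) * m + 1)
    for i in range(n - 1):
        fine[i * m : (i + 1) * m] = np.linspace(
            obs_times[i], obs_times[i + 1], m, endpoint=False
        )
    fine[-1] = obs_times[-1]
    obs_index = np.arange(n) * m
    return fine, obs_index


def simulate_continuous(
    params: MovementParams,
    obs_times: np.ndarray,
    substeps: int = 200,
    v0: np.ndarray | None = None,
    x0: np.ndarray = (0.0, 0.0),
    seed=None,
    exact: bool = False,
) -> TruePath:
    """Simulate the latent track between and at the given observation times.

    Inserts ``substeps`` equally spaced fine-grid points between consecutive
    observation times and integrates the velocity SDE by Euler-Maruyama:
    ``V[k+1] = V[k] - Theta (V[k] - mu) d + S sqrt(d) Z[k]`` and
    ``X[k+1] = X[k] + V[k] d``.  With ``exact=True`` the velocity instead
    uses the exact Ornstein-Uhlenbeck transition on each fine step (a
    verification path for tests); the location update is unchanged.

    ``v0`` defaults to a draw from the stationary velocity distribution
    ``N(mu, C)`` (falling back to ``mu`` when no stationary covariance
    exists); ``x0`` defaults to the origin.
    """
    obs_times = np.asarray(obs_times, dtype=float)
    if obs_times.ndim != 1 or np.any(np.diff(obs_times) <= 0):
        raise ValueError("obs_times must be strictly increasing")
    if substeps < 0:
        raise ValueError("substeps must be nonnegative")
    rng = np.random.default_rng(seed)
    from .kinematics import theta_matrix

    Th = theta_matrix(params)
    if v0 is None:
        try:
            C = stationary_velocity_cov(params)
            v0 = rng.multivariate_normal(params.mu, C)
        except ValueError:
            v0 = params.mu.copy()
    v0 = np.asarray(v0, dtype=float).reshape(2)
    x0 = np.asarray(x0, dtype=float).reshape(2)

    fine, obs_index = _fine_grid(obs_times, substeps)
    Z = rng.standard_normal((fine.shape[0] - 1, 2))
    if not exact:
        # pack drift: row i of Thb is [Th_i0, Th_i1, (Th @ mu)_i]
        Thb = np.column_stack([Th, Th @ params.mu])
        X, V = _euler_core(fine, v0, x0, Thb, params.S, Z)
    else:
        n = fine.shape[0]
        X = np.empty((n, 2))
        V = np.empty((n, 2))
        X[0], V[0] = x0, v0
        for k in range(n - 1):
            d = fine[k + 1] - fine[k]
            A = propagator(params, d)
            Vcov = increment_velocity_cov(params, d)
            L = np.linalg.cholesky(Vcov + 1e-300 * np.eye(2))
            V[k + 1] = params.mu + A @ (V[k] - params.mu) + L @ Z[k]
            X[k + 1] = X[k] + V[k] * d
    return TruePath(fine, X, V, obs_index)


def simulate_observations(
    path: TruePath,
    noise: NoiseModel | None = None,
    classes: np.ndarray | None = None,
    seed=None,
) -> ObservationSet:
    """Add measurement error to the true locations at the observation times.

    Gaussian mode draws ``Y = X + N(0, scale)``; Student-t mode draws
    bivariate-t errors with the per-class scale matrix and degrees of
    freedom.  ``classes`` assigns one noise-class label per observation
    (default: all "G" for Gaussian, else cycling through the classes the
    noise model defines).
    """
    noise = noise or NoiseModel.gaussian()
    rng = np.random.default_rng(seed)
    t = path.obs_times
    X = path.obs_locations
    n = t.shape[0]
    if classes is None:
        if noise.kind == "gaussian" and "G" in noise.scales:
            classes = np.full(n, "G", dtype=object)
        else:
            labels = list(noise.scales)
            classes = np.array([labels[i % len(labels)] for i in range(n)], object)
    classes = np.asarray(classes, dtype=object)
    Y = X.copy()
    for label in np.unique(classes):
        idx = np.flatnonzero(classes == label)
        M = noise.scale_for(str(label))
        # eigen square root: tolerates singular (even zero) scale matrices
        w, V = np.linalg.eigh(M)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        eta = rng.standard_normal((idx.size, 2)) @ L.T
        if noise.kind == "student_t":
            df = noise.dfs[str(label)]
            u = rng.chisquare(df, idx.size) / df
            eta /= np.sqrt(u)[:, None]
        Y[idx] += eta
    return ObservationSet(t, Y, classes)
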