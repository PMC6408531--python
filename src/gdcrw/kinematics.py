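"""Closed-form kinematics of the correlated-velocity process.

Everything here is a deterministic function of :class:`~gdcrw.params.MovementParams`
and a time step: the mean-reversion matrix ``Theta``, its matrix-exponential
propagator ``exp(-Theta dt)``, the stationary velocity covariance ``C`` solving
``Theta C + C Theta^T = Sigma``, the covariance of velocity increments, the
regular-step rotation-decay reduction, and the time-scale correction mapping
regular-step parameter estimates to a per-unit-time scale.
"""

from __future__ import annotations

import numpy as np

from .params import MovementParams

__all__ = [
    "theta_matrix",
    "propagator",
    "propagator_many",
    "stationary_velocity_cov",
    "increment_velocity_cov",
    "dcrw_reduction",
    "correct_dcrw_params",
]


def theta_matrix(params: MovementParams) -> np.ndarray:
    """Mean-reversion matrix ``[[-log g1, theta], [-theta, -log g2]]``."""
    return np.array(
        [
            [-np.log(params.gamma1), params.theta],
            [-params.theta, -np.log(params.gamma2)],
        ]
    )


def _expm2(M: np.ndarray) -> np.ndarray:
    """Exact exponential of a single 2x2 matrix.

    Uses the trace/determinant decomposition: with ``a = tr(M)/2`` and
    ``B = M - a I`` (traceless, so ``B^2 = (a^2 - det M) I``),
    ``exp(M) = e^a (cosh(s) I + sinh(s)/s B)`` where ``s^2 = a^2 - det M``.
    The ``s^2 < 0`` branch turns cosh/sinh into cos/sinc, and ``s -> 0`` is
    the degenerate (equal-eigenvalue) limit.
    """
    a = 0.5 * (M[0, 0] + M[1, 1])
    detM = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    s2 = a * a - detM
    B = M - a * np.eye(2)
    if s2 > 1e-300:
        s = np.sqrt(s2)
        c, sc = np.cosh(s), np.sinh(s) / s
    elif s2 < -1e-300:
        w = np.sqrt(-s2)
        c, sc = np.cos(w), np.sin(w) / w
    else:
        c, sc = 1.0, 1.0
    return np.exp(a) * (c * np.eye(2) + sc * B)


def propagator(params: MovementParams, dt: float) -> np.ndarray:
    """Velocity propagator ``exp(-Theta dt)`` over a step of length ``dt``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return _expm2(-theta_matrix(params) * dt)


def propagator_many(params: MovementParams, dts: np.ndarray) -> np.ndarray:
    """Vectorized ``exp(-Theta dt)`` for an array of steps; returns (n, 2, 2)."""
    dts = np.asarray(dts, dtype=float)
    Th = theta_matrix(params)
    a = -0.5 * (Th[0, 0] + Th[1, 1]) * dts
    detM = (Th[0, 0] * Th[1, 1] - Th[0, 1] * Th[1, 0]) * dts * dts
    s2 = a * a - detM
    s = np.sqrt(np.abs(s2))
    pos = s2 > 0
    c = np.where(pos, np.cosh(s), np.cos(s))
    with np.errstate(invalid="ignore", divide="ignore"):
        sc = np.where(pos, np.sinh(s) / s, np.sin(s) / s)
    sc = np.where(s < 1e-150, 1.0, sc)
    B = -Th[None, :, :] * dts[:, None, None] - a[:, None, None] * np.eye(2)
    out = np.exp(a)[:, None, None] * (
        c[:, None, None] * np.eye(2) + sc[:, None, None] * B
    )
    return out


def stationary_velocity_cov(params: MovementParams) -> np.ndarray:
    """Stationary velocity covariance ``C``.

    Solves ``vec(C) = (Theta (+) Theta)^{-1} vec(Sigma)`` where ``(+)`` is the
    Kronecker sum, equivalently the Lyapunov equation
    ``Theta C + C Theta^T = Sigma``.  Requires mean reversion in at least one
    coordinate (``gamma1 < 1`` or ``gamma2 < 1``); the pure-rotation case has
    no stationary covariance.
    """
    Th = theta_matrix(params)
    I2 = np.eye(2)
    ksum = np.kron(Th, I2) + np.kron(I2, Th)
    if np.linalg.cond(ksum) > 1e12:
        raise ValueError(
            "no stationary covariance: Theta (+) Theta is singular "
            "(requires gamma1 < 1 or gamma2 < 1)"
        )
    # vec() stacks columns: reshape with Fortran order.
    vecC = np.linalg.solve(ksum, params.Sigma.reshape(-1, order="F"))
    C = vecC.reshape(2, 2, order="F")
    return 0.5 * (C + C.T)


def increment_velocity_cov(params: MovementParams, dt: float) -> np.ndarray:
    """Covariance of the velocity increment noise over a step ``dt``.

    ``C - exp(-Theta dt) C exp(-Theta^T dt)``: zero at ``dt = 0``, growing to
    the stationary covariance ``C`` as ``dt`` increases, and approximately
    ``Sigma * dt`` for small steps.
    """
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    C = stationary_velocity_cov(params)
    if dt == 0:
        return np.zeros((2, 2))
    A = propagator(params, dt)
    V = C - A @ C @ A.T
    return 0.5 * (V + V.T)


def dcrw_reduction(params: MovementParams, dt: float) -> np.ndarray:
    """Regular-step rotation-decay form of the propagator.

    With equal autocorrelations ``gamma1 = gamma2 = gamma`` the propagator has
    the closed form ``R(theta dt) * gamma^dt`` with rotation matrix
    ``R(phi) = [[cos phi, -sin phi], [sin phi, cos phi]]`` — the transition
    matrix of the classic regular-step first-difference correlated random
    walk.  The result is cross-checked against :func:`propagator`.
    """
    if params.gamma1 != params.gamma2:
        raise ValueError("dcrw_reduction requires gamma1 == gamma2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    phi = params.theta * dt
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    out = R * params.gamma1**dt
    assert np.max(np.abs(out - propagator(params, dt))) < 1e-12
    return out


def correct_dcrw_params(
    gamma_tilde: float, theta_tilde: float, dt_tilde: float
) -> tuple[float, float]:
    """Rescale regular-step parameter estimates to a per-time-unit scale.

    A regular-step model fitted with step length ``dt_tilde`` estimates an
    autocorrelation and rotation *per step*; the time-scale-invariant values
    are ``gamma = gamma_tilde**(1/dt_tilde)`` and
    ``theta = theta_tilde / dt_tilde``.
    """
    if gamma_tilde <= 0:
        raise ValueError("gamma_tilde must be positive")
    if dt_tilde <= 0:
        raise ValueError("dt_tilde must be positive")
    return gamma_tilde ** (1.0 / dt_tilde), theta_tilde / dt_tilde
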