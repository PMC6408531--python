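"""Movement-model parameters.

The velocity of an animal is modelled by the bivariate Ornstein-Uhlenbeck
stochastic differential equation

    dV_t = -Theta (V_t - mu) dt + S dB_t,

where ``Theta = [[-log g1, theta], [-theta, -log g2]]`` combines per-coordinate
autocorrelation (``g1``, ``g2``) with a rotation rate ``theta`` (radians per
time unit), ``mu`` is a mean (drift) velocity and ``S`` is a lower-triangular
matrix whose outer product ``Sigma = S S^T`` is the velocity noise covariance.
The location is the integrated velocity, ``dX_t = V_t dt``.

The first model coordinate is latitude ("y") and the second longitude ("x");
swapping the coordinate order only flips the sign of ``theta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MovementParams"]


@dataclass(frozen=True)
class MovementParams:
    """Parameters of the continuous-time correlated-velocity movement model.

    Parameters
    ----------
    gamma1, gamma2 : float
        Autocorrelation of the velocity in the first / second coordinate over
        one time unit; must lie in ``(0, 1]``.  Values near one give
        persistent movement, values near zero reduce the model to a random
        walk.
    theta : float
        Rotation parameter (radians per time unit).  Combined with the
        autocorrelation it controls the mean turning angle; nonzero values
        produce tortuous, circling tracks.
    mu : array-like of shape (2,)
        Mean velocity (drift), in distance per time unit.
    S : array-like of shape (2, 2)
        Lower-triangular noise loading with positive diagonal;
        ``Sigma = S @ S.T``.
    """

    gamma1: float
    gamma2: float
    theta: float = 0.0
    mu: np.ndarray = field(default_factory=lambda: np.zeros(2))
    S: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma1 <= 1.0 and 0.0 < self.gamma2 <= 1.0):
            raise ValueError(
                f"autocorrelations must be in (0, 1]; got "
                f"gamma1={self.gamma1}, gamma2={self.gamma2}"
            )
        mu = np.asarray(self.mu, dtype=float).reshape(2)
        S = np.asarray(self.S, dtype=float)
        if S.shape != (2, 2):
            raise ValueError("S must be a 2x2 matrix")
        if S[0, 1] != 0.0:
            raise ValueError("S must be lower triangular (S[0,1] == 0)")
        if S[0, 0] <= 0.0 or S[1, 1] <= 0.0:
            raise ValueError("S must have a positive diagonal")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "S", S)

    @property
    def Sigma(self) -> np.ndarray:
        """Velocity noise covariance ``S @ S.T``."""
        return self.S @ self.S.T

    @classmethod
    def isotropic(
        cls,
        gamma: float,
        sigma: float,
        theta: float = 0.0,
        mu: tuple[float, float] = (0.0, 0.0),
    ) -> "MovementParams":
        """Equal autocorrelation and equal, independent noise per coordinate."""
        return cls(gamma, gamma, theta, np.asarray(mu, float), np.eye(2) * sigma)
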