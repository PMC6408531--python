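"""Measurement-error models for telemetry observations.

Observations are the true location plus a zero-mean error that is either
bivariate Gaussian (GPS-grade data, or the simulation studies) or bivariate
Student-t with a per-Argos-class scale matrix and degrees of freedom (heavy
tails for poor location classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseModel", "default_argos_noise"]


@dataclass
class NoiseModel:
    """Per-class measurement error specification.

    Parameters
    ----------
    kind : {"gaussian", "student_t"}
        Error family.  Gaussian errors admit an exact Kalman likelihood;
        Student-t errors are handled by the Laplace approximation.
    scales : dict
        Class label -> 2x2 symmetric positive-definite scale matrix
        (squared measurement units).  For Gaussian errors this is the
        covariance; for t errors the t scale matrix.
    dfs : dict
        Class label -> degrees of freedom (> 0); t errors only.
    estimate : bool
        Whether the scale (and df, for t) parameters are estimated during
        fitting or held fixed at the given values.
    """

    kind: str = "gaussian"
    scales: dict = field(default_factory=lambda: {"G": 0.1**2 * np.eye(2)})
    dfs: dict = field(default_factory=dict)
    estimate: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "student_t"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        for k, M in self.scales.items():
            M = np.asarray(M, dtype=float)
            if M.shape != (2, 2) or not np.allclose(M, M.T):
                raise ValueError(f"scale for class {k!r} must be symmetric 2x2")
            # PSD is enough for simulation; fitting additionally needs PD
            if np.any(np.linalg.eigvalsh(M) < 0):
                raise ValueError(f"scale for class {k!r} must be positive semidefinite")
            self.scales[k] = M
        if self.kind == "student_t":
            for k in self.scales:
                if k not in self.dfs:
                    raise ValueError(f"missing degrees of freedom for class {k!r}")
                if self.dfs[k] <= 0:
                    raise ValueError("degrees of freedom must be positive")

    @classmethod
    def gaussian(cls, sd: float = 0.1, estimate: bool = True) -> "NoiseModel":
        """Isotropic Gaussian errors with standard deviation ``sd``."""
        return cls("gaussian", {"G": sd**2 * np.eye(2)}, {}, estimate)

    def scale_for(self, label: str) -> np.ndarray:
        if label in self.scales:
            return self.scales[label]
        raise KeyError(f"unknown noise class {label!r}")


def default_argos_noise(estimate: bool = True) -> NoiseModel:
    """Illustrative per-class t-error defaults for Argos-style data.

    Synthetic defaults: scale standard deviations grow and tails get heavier
    from the best class ("3") to the worst ("B").  Intended as a starting
    point for simulation and fitting demos; real analyses should estimate
    these from data (the default) or supply calibrated values.
    """
    sds = {"3": 0.05, "2": 0.08, "1": 0.12, "0": 0.25, "A": 0.35, "B": 0.5}
    dfs = {"3": 15.0, "2": 10.0, "1": 8.0, "0": 5.0, "A": 4.0, "B": 3.0}
    scales = {k: sd**2 * np.eye(2) for k, sd in sds.items()}
    return NoiseModel("student_t", scales, dfs, estimate)
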