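"""In-memory containers for tracks and telemetry observations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TruePath", "ObservationSet", "ARGOS_CLASSES"]

#: Argos location-quality classes, best to worst, plus "G" for GPS/Gaussian
#: grade records.  Class "Z" (invalid) is dropped on load.
ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B")


@dataclass
class TruePath:
    """A simulated latent track on a fine time grid.

    ``times`` are strictly increasing; ``locations[k]`` satisfies the Euler
    update ``X[k+1] = X[k] + V[k] * (times[k+1] - times[k])`` exactly.
    ``obs_index`` marks the fine-grid indices corresponding to observation
    times.
    """

    times: np.ndarray
    locations: np.ndarray
    velocities: np.ndarray
    obs_index: np.ndarray

    @property
    def obs_times(self) -> np.ndarray:
        return self.times[self.obs_index]

    @property
    def obs_locations(self) -> np.ndarray:
        return self.locations[self.obs_index]


@dataclass
class ObservationSet:
    """Irregularly timed bivariate observations of one track.

    ``times`` are nondecreasing (fractional time units since the first
    record); ``coords`` is (n, 2) with the first coordinate latitude/"y";
    ``classes`` holds one noise-class label per record ("G" for
    Gaussian-grade, or an Argos class 3/2/1/0/A/B).
    """

    times: np.ndarray
    coords: np.ndarray
    classes: np.ndarray = field(default=None)  # type: ignore[assignment]
    track_id: str = "track"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.times.shape[0]
        if self.coords.shape != (n, 2):
            raise ValueError("coords must have shape (n, 2)")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("observation times must be nondecreasing")
        if self.classes is None:
            self.classes = np.full(n, "G", dtype=object)
        else:
            self.classes = np.asarray(self.classes, dtype=object)
            if self.classes.shape[0] != n:
                raise ValueError("one class label per record is required")

    def __len__(self) -> int:
        return self.times.shape[0]
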