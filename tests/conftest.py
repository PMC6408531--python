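import numpy as np
import pytest

from gdcrw import (
    MovementParams,
    NoiseModel,
    ObservationSet,
    sample_observation_times,
    simulate_continuous,
    simulate_observations,
)


@pytest.fixture
def persistent_params():
    return MovementParams.isotropic(0.9, np.exp(-2))


@pytest.fixture
def tortuous_params():
    return MovementParams.isotropic(0.6, np.exp(-2), theta=np.pi / 3)


def make_track(params, n_obs=80, obs_sd=0.1, seed=0, substeps=60):
    """Simulated observations plus the generating path (shared helper)."""
    times = sample_observation_times(n_obs, seed=np.random.default_rng((seed, 0)))
    path = simulate_continuous(
        params, times, substeps=substeps, seed=np.random.default_rng((seed, 1))
    )
    obs = simulate_observations(
        path, NoiseModel.gaussian(obs_sd), seed=np.random.default_rng((seed, 2))
    )
    return path, obs


@pytest.fixture
def small_track(persistent_params):
    return make_track(persistent_params, n_obs=60, seed=5)


def random_params(rng, allow_rotation=True):
    g1, g2 = rng.uniform(0.3, 0.95, 2)
    theta = rng.uniform(-1.0, 1.0) if allow_rotation else 0.0
    mu = rng.normal(0, 0.3, 2)
    S = np.array([[rng.uniform(0.1, 0.5), 0.0], [rng.normal(0, 0.1), rng.uniform(0.1, 0.5)]])
    return MovementParams(g1, g2, theta, mu, S)


def random_obsset(rng, n_obs, span=10.0):
    times = np.sort(rng.uniform(0, span, n_obs))
    times[0] = 0.0
    coords = rng.normal(0, 1.0, (n_obs, 2))
    return ObservationSet(times, coords)
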