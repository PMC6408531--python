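"""Grid construction, interpolation weights and state-system assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdcrw import (
    MovementParams,
    ObservationSet,
    assemble_system,
    build_grid_aligned,
    build_grid_regular,
    interpolation_weights,
    sample_observation_times,
)


class TestAlignedGrid:
    def test_recursive_midpoints_with_tie_rule(self):
        grid = build_grid_aligned([0.0, 4.0, 6.0], extra_total=2)
        # first midpoint splits [0,4] at 2; the tie among [0,2],[2,4],[4,6]
        # breaks to the earliest gap, adding 1
        assert np.allclose(grid.times, [0.0, 1.0, 2.0, 4.0, 6.0])
        assert list(grid.aligned) == [True, False, False, True, True]

    def test_obs_only(self):
        grid = build_grid_aligned([0.0, 1.0, 2.0])
        assert np.allclose(grid.times, [0.0, 1.0, 2.0])
        assert grid.aligned.all()

    def test_spacing_count_on_typical_track(self):
        # a ~497.5-unit track gains about one auxiliary point per 8 units
        times = sample_observation_times(250, seed=123)
        times = times * (497.5 / times[-1])
        grid = build_grid_aligned(times, extra_spacing=8.0)
        n_aux = int((~grid.aligned).sum())
        assert 58 <= n_aux <= 63

    def test_duplicate_obs_collapse(self):
        grid = build_grid_aligned([0.0, 1.0, 1.0, 2.0])
        assert len(grid) == 3

    def test_exclusive_options(self):
        with pytest.raises(ValueError):
            build_grid_aligned([0.0, 1.0], extra_spacing=1.0, extra_total=2)


class TestRegularGrid:
    def test_even_spacing(self):
        grid = build_grid_regular([0.0, 3.0, 10.0], 5)
        assert np.allclose(grid.times, [0.0, 2.5, 5.0, 7.5, 10.0])

    def test_step_for_study_dimensions(self):
        grid = build_grid_regular([0.0, 497.5], 250)
        assert grid.deltas[0] == pytest.approx(497.5 / 249, rel=1e-12)
        assert grid.deltas[0] == pytest.approx(1.998, abs=2e-3)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            build_grid_regular([0.0, 1.0], 2)


class TestInterpolationWeights:
    def test_midpoint(self):
        grid = build_grid_aligned([1.0, 2.0])
        idx, q = interpolation_weights([1.5], grid)
        assert idx[0] == 0 and q[0] == pytest.approx(0.5)

    def test_on_grid_point(self):
        grid = build_grid_aligned([0.0, 1.0, 2.0])
        idx, q = interpolation_weights([1.0], grid)
        assert idx[0] == 1 and q[0] == 0.0

    def test_last_point_closure(self):
        grid = build_grid_aligned([0.0, 1.0, 2.0])
        idx, q = interpolation_weights([2.0], grid)
        assert idx[0] == 1 and q[0] == pytest.approx(1.0)

    def test_outside_span_rejected(self):
        grid = build_grid_aligned([0.0, 2.0])
        with pytest.raises(ValueError):
            interpolation_weights([3.0], grid)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_affine_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 10, 8))
        t[0], t[-1] = 0.0, 10.0
        grid = build_grid_aligned(np.unique(t))
        s = rng.uniform(0, 10, 20)
        idx, q = interpolation_weights(s, grid)
        rebuilt = (1 - q) * grid.times[idx] + q * grid.times[idx + 1]
        assert np.max(np.abs(rebuilt - s)) < 1e-12


def _obsset(times, coords=None):
    times = np.asarray(times, float)
    if coords is None:
        coords = np.zeros((times.size, 2))
    return ObservationSet(times, coords)


class TestAssembleSystem:
    def test_regular_equal_gamma_reduces_to_rotation_decay(self):
        # with regular unit steps and mu = 0 the leading block implements
        # X_i = X_{i-1} + R(theta) gamma (X_{i-1} - X_{i-2})
        p = MovementParams(0.8, 0.8, 0.4)
        obs = _obsset(np.arange(5.0))
        grid = build_grid_aligned(obs.times)
        sys = assemble_system(p, grid, obs, "aligned")
        phi, g = 0.4, 0.8
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        expected = np.eye(2) + R * g
        assert np.allclose(sys.T[0, :2, :2], expected, atol=1e-12)
        assert np.allclose(sys.T[0, :2, 2:], -R * g, atol=1e-12)
        assert np.allclose(sys.c, 0.0)

    def test_drifted_random_walk_limit(self):
        # gamma -> 0: propagator vanishes, offset tends to step * drift
        p = MovementParams(1e-8, 1e-8, 0.0, mu=(1.0, 0.0))
        obs = _obsset([0.0, 1.5, 3.5])
        grid = build_grid_aligned(obs.times)
        sys = assemble_system(p, grid, obs, "aligned")
        assert np.allclose(sys.c[0, :2], [2.0, 0.0], atol=1e-6)
        assert np.allclose(sys.T[0, :2, :2], np.eye(2), atol=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_process_cov_psd_on_irregular_grids(self, seed):
        rng = np.random.default_rng(seed)
        times = np.concatenate([[0.0], np.cumsum(rng.uniform(0.05, 4.0, 12))])
        p = MovementParams(
            rng.uniform(0.2, 0.95), rng.uniform(0.2, 0.95), rng.uniform(-1.5, 1.5)
        )
        obs = _obsset(times)
        sys = assemble_system(p, build_grid_aligned(times), obs, "aligned")
        for Q in sys.Q:
            assert np.min(np.linalg.eigvalsh(Q[:2, :2])) > -1e-12

    def test_refinement_keeps_observation_loadings(self, persistent_params):
        obs = _obsset([0.0, 2.0, 5.0, 9.0])
        coarse = build_grid_aligned(obs.times)
        fine = build_grid_aligned(obs.times, extra_total=4)
        s1 = assemble_system(persistent_params, coarse, obs, "aligned")
        s2 = assemble_system(persistent_params, fine, obs, "aligned")
        t1 = [coarse.times[k + 1] for k in s1.obs_state]
        t2 = [fine.times[k + 1] for k in s2.obs_state]
        # all but the first observation load the first block of their state
        assert t1[1:] == [2.0, 5.0, 9.0] and t2[1:] == [2.0, 5.0, 9.0]

    def test_duplicate_times_share_state(self, persistent_params):
        obs = _obsset([0.0, 1.0, 1.0, 2.0])
        grid = build_grid_aligned(obs.times)
        sys = assemble_system(persistent_params, grid, obs, "aligned")
        assert sys.obs_state[1] == sys.obs_state[2]

    def test_aligned_requires_obs_on_grid(self, persistent_params):
        obs = _obsset([0.0, 0.7, 2.0])
        grid = build_grid_aligned([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            assemble_system(persistent_params, grid, obs, "aligned")

    def test_interpolated_weights_are_convex(self, persistent_params):
        obs = _obsset([0.0, 0.7, 1.3, 2.0])
        grid = build_grid_regular(obs.times, 3)
        sys = assemble_system(persistent_params, grid, obs, "interpolated")
        w = sys.H[:, 0, [0, 2]]
        assert np.allclose(w.sum(axis=1), 1.0)
        assert np.all((w >= 0) & (w <= 1))
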