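"""Likelihood and smoothing against independent dense-joint oracles,
Laplace/Kalman agreement, the exact continuous-time model, and fitting."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from gdcrw import (
    GridSpec,
    ModelSpec,
    MovementParams,
    NoiseModel,
    ObservationSet,
    assemble_system,
    build_grid_aligned,
    fit,
    fit_ctcrw,
    kalman_loglik,
    kalman_smooth,
    laplace_loglik,
)
from gdcrw.ctcrw import ctcrw_loglik, ctcrw_step

from conftest import make_track


# ---------------------------------------------------------------------------
# dense-joint oracle: the stacked states are jointly Gaussian, so the
# marginal of the observations can be computed directly from the system
# matrices without any filtering


def dense_joint_moments(system):
    n = system.n_states
    m = np.zeros(4 * n)
    S = np.zeros((4 * n, 4 * n))
    m[:4] = system.a0
    S[:4, :4] = system.P0
    for k in range(1, n):
        T = system.T[k - 1]
        m[4 * k : 4 * k + 4] = T @ m[4 * (k - 1) : 4 * k] + system.c[k - 1]
        # cross-covariances with every earlier state
        for l in range(k):
            S[4 * k : 4 * k + 4, 4 * l : 4 * l + 4] = (
                T @ S[4 * (k - 1) : 4 * k, 4 * l : 4 * l + 4]
            )
            S[4 * l : 4 * l + 4, 4 * k : 4 * k + 4] = S[
                4 * k : 4 * k + 4, 4 * l : 4 * l + 4
            ].T
        S[4 * k : 4 * k + 4, 4 * k : 4 * k + 4] = (
            T @ S[4 * (k - 1) : 4 * k, 4 * (k - 1) : 4 * k] @ T.T + system.Q[k - 1]
        )
    return m, S


def dense_obs_moments(system):
    m, S = dense_joint_moments(system)
    n_obs = system.y.shape[0]
    W = np.zeros((2 * n_obs, 4 * system.n_states))
    R = np.zeros((2 * n_obs, 2 * n_obs))
    for j in range(n_obs):
        k = system.obs_state[j]
        W[2 * j : 2 * j + 2, 4 * k : 4 * k + 4] = system.H[j]
        R[2 * j : 2 * j + 2, 2 * j : 2 * j + 2] = system.R[j]
    mean_y = W @ m
    cov_y = W @ S @ W.T + R
    return m, S, W, mean_y, cov_y


def oracle_loglik(system):
    _, _, _, mean_y, cov_y = dense_obs_moments(system)
    return multivariate_normal(mean_y, cov_y).logpdf(system.y.reshape(-1))


def oracle_smooth_locations(system):
    m, S, W, mean_y, cov_y = dense_obs_moments(system)
    resid = system.y.reshape(-1) - mean_y
    m_post = m + S @ W.T @ np.linalg.solve(cov_y, resid)
    n = system.n_states
    locs = np.empty((n + 1, 2))
    locs[0] = m_post[2:4]
    for k in range(n):
        locs[k + 1] = m_post[4 * k : 4 * k + 2]
    return locs


def moderate_system(params, times, coords, mode="aligned", obs_cov=None, seed=0):
    """Assemble a system, replacing the diffuse prior by a moderate one so
    oracle comparisons are not limited by conditioning."""
    obs = ObservationSet(times, coords)
    if mode == "aligned":
        grid = build_grid_aligned(times)
    else:
        from gdcrw import build_grid_regular

        grid = build_grid_regular(times, max(3, len(times) - 2))
    sys = assemble_system(params, grid, obs, mode, noise_cov=obs_cov)
    sys.P0 = sys.P0 - 1e8 * np.kron(np.ones((2, 2)), np.eye(2)) + 4.0 * np.kron(
        np.ones((2, 2)), np.eye(2)
    )
    sys.P0[np.diag_indices(4)] += 1e-9
    return sys


class TestKalmanAgainstDenseOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_loglik_matches(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        times = np.concatenate([[0.0], np.cumsum(rng.uniform(0.2, 3.0, n - 1))])
        coords = rng.normal(0, 1, (n, 2))
        p = MovementParams(
            rng.uniform(0.3, 0.95), rng.uniform(0.3, 0.95), rng.uniform(-1, 1),
            rng.normal(0, 0.2, 2),
            np.array([[rng.uniform(0.1, 0.5), 0], [0, rng.uniform(0.1, 0.5)]]),
        )
        sys = moderate_system(p, times, coords, obs_cov=0.2**2 * np.eye(2))
        assert kalman_loglik(sys) == pytest.approx(oracle_loglik(sys), abs=1e-8)

    def test_loglik_with_duplicate_times(self, persistent_params):
        # two fixes in the same burst share a latent state; the filter's
        # sequential updates must equal the stacked joint density
        rng = np.random.default_rng(3)
        times = np.array([0.0, 1.0, 1.0, 2.5, 4.0])
        coords = rng.normal(0, 1, (5, 2))
        sys = moderate_system(persistent_params, times, coords, obs_cov=0.1**2 * np.eye(2))
        assert kalman_loglik(sys) == pytest.approx(oracle_loglik(sys), abs=1e-8)

    def test_loglik_interpolated_mode(self, persistent_params):
        rng = np.random.default_rng(4)
        times = np.array([0.0, 0.9, 1.7, 2.2, 3.4, 4.9])
        coords = rng.normal(0, 1, (6, 2))
        sys = moderate_system(
            persistent_params, times, coords, mode="interpolated",
            obs_cov=0.15**2 * np.eye(2),
        )
        assert kalman_loglik(sys) == pytest.approx(oracle_loglik(sys), abs=1e-8)

    def test_single_observation_prior_predictive(self, persistent_params):
        # one fix at the first grid point: the marginal is just the
        # prior-predictive Gaussian at that state
        times = np.array([0.0, 1.0])
        coords = np.array([[0.3, -0.2], [0.0, 0.0]])
        obs = ObservationSet(times[:1], coords[:1])
        grid = build_grid_aligned(times)
        sys = assemble_system(persistent_params, grid, obs, "aligned",
                              noise_cov=0.1**2 * np.eye(2))
        expected = multivariate_normal(
            sys.a0[2:], sys.P0[2:, 2:] + sys.R[0]
        ).logpdf(coords[0])
        assert kalman_loglik(sys) == pytest.approx(expected, rel=1e-10)

    def test_smoother_matches_conditional_mean(self, tortuous_params):
        rng = np.random.default_rng(9)
        times = np.concatenate([[0.0], np.cumsum(rng.uniform(0.3, 2.0, 6))])
        coords = rng.normal(0, 1, (7, 2))
        sys = moderate_system(tortuous_params, times, coords, obs_cov=0.1**2 * np.eye(2))
        _, locs, var = kalman_smooth(sys)
        assert np.max(np.abs(locs - oracle_smooth_locations(sys))) < 1e-8
        assert np.all(var >= -1e-12)

    def test_zero_noise_smoothing_interpolates_observations(self, persistent_params):
        path, obs = make_track(persistent_params, n_obs=30, seed=2)
        obs.coords = path.obs_locations.copy()  # noise-free fixes
        grid = build_grid_aligned(obs.times)
        sys = assemble_system(persistent_params, grid, obs, "aligned",
                              noise_cov=1e-12 * np.eye(2))
        _, locs, _ = kalman_smooth(sys)
        assert np.max(np.abs(locs - obs.coords)) < 1e-4

    def test_smoothing_never_exceeds_filtering_uncertainty(self, persistent_params):
        from gdcrw._kalman import filter4, smooth4

        path, obs = make_track(persistent_params, n_obs=25, seed=8)
        grid = build_grid_aligned(obs.times)
        sys = assemble_system(persistent_params, grid, obs, "aligned",
                              noise_cov=0.1**2 * np.eye(2))
        _, ok, pa, pP, fa, fP = filter4(
            sys.a0, sys.P0, sys.T, sys.c, sys.Q, sys.obs_state, sys.H, sys.y,
            sys.R, sys.n_states, True,
        )
        assert ok
        sa, sP = smooth4(sys.T, pa, pP, fa, fP)
        for k in range(sys.n_states):
            assert np.min(np.linalg.eigvalsh(fP[k] - sP[k])) > -1e-6


class TestLaplace:
    def test_gaussian_noise_equals_kalman(self, persistent_params):
        path, obs = make_track(persistent_params, n_obs=25, seed=4)
        grid = build_grid_aligned(obs.times)
        sys = assemble_system(persistent_params, grid, obs, "aligned",
                              noise_cov=0.1**2 * np.eye(2))
        assert laplace_loglik(sys) == pytest.approx(kalman_loglik(sys), abs=1e-6)

    def test_gaussian_interpolated_equals_kalman(self, tortuous_params):
        from gdcrw import build_grid_regular

        path, obs = make_track(tortuous_params, n_obs=25, seed=5)
        grid = build_grid_regular(obs.times, 20)
        sys = assemble_system(tortuous_params, grid, obs, "interpolated",
                              noise_cov=0.1**2 * np.eye(2))
        assert laplace_loglik(sys) == pytest.approx(kalman_loglik(sys), abs=1e-6)

    def test_t_approaches_gaussian_as_df_grows(self, persistent_params):
        path, obs = make_track(persistent_params, n_obs=20, seed=6)
        grid = build_grid_aligned(obs.times)
        sys = assemble_system(persistent_params, grid, obs, "aligned",
                              noise_cov=0.1**2 * np.eye(2))
        ll_g = kalman_loglik(sys)
        scales = np.broadcast_to(0.1**2 * np.eye(2), (len(obs), 2, 2))
        gaps = []
        for df in (1e2, 1e4, 1e6):
            ll_t = laplace_loglik(sys, scales, np.full(len(obs), df))
            gaps.append(abs(ll_t - ll_g))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-3

    def test_t_marginal_against_importance_sampling(self, persistent_params):
        # N = 6 latent locations, heavy-tailed errors: compare the Laplace
        # value to a Monte-Carlo estimate of the true marginal
        rng = np.random.default_rng(12)
        times = np.array([0.0, 1.0, 2.2, 3.1, 4.5, 5.5])
        path, obs_full = make_track(persistent_params, n_obs=6, seed=7)
        obs = ObservationSet(times, obs_full.coords)
        sys = moderate_system(persistent_params, times, obs.coords,
                              obs_cov=0.2**2 * np.eye(2))
        scales = np.broadcast_to(0.2**2 * np.eye(2), (6, 2, 2)).copy()
        dfs = np.full(6, 4.0)
        ll_lap = laplace_loglik(sys, scales, dfs)

        # importance sampling: heavy-tailed proposal centred on the
        # Gaussian-noise posterior of the locations (the weights correct for
        # the mismatch, so the estimate targets the true t-error marginal)
        from scipy.stats import multivariate_t

        m, S = dense_joint_moments(sys)
        _, _, W, mean_y, cov_y = dense_obs_moments(sys)
        K = S @ W.T @ np.linalg.inv(cov_y)
        m_post = m + K @ (sys.y.reshape(-1) - mean_y)
        S_post = S - K @ W @ S
        loc_idx = [2, 3] + sum(([4 * k, 4 * k + 1] for k in range(sys.n_states)), [])
        mz = m_post[loc_idx]
        Sz = S_post[np.ix_(loc_idx, loc_idx)]
        Sz = 0.5 * (Sz + Sz.T) + 1e-10 * np.eye(12)
        prop = multivariate_t(mz, 2.0 * Sz, df=5)
        n_draws = 400_000
        draws = prop.rvs(n_draws, random_state=rng)
        Sp = S[np.ix_(loc_idx, loc_idx)]
        prior = multivariate_normal(m[loc_idx], 0.5 * (Sp + Sp.T))
        logw = prior.logpdf(draws) - prop.logpdf(draws)
        # z ordering: X_1, X_2, ..., X_N
        for j in range(6):
            k = sys.obs_state[j]
            w_next, w_cur = sys.H[j, 0, 0], sys.H[j, 0, 2]
            pred = (
                w_cur * draws[:, 2 * k : 2 * k + 2]
                + w_next * draws[:, 2 * k + 2 : 2 * k + 4]
            )
            logw += multivariate_t(np.zeros(2), scales[j], df=dfs[j]).logpdf(
                sys.y[j] - pred
            )
        ll_mc = logsumexp(logw) - np.log(n_draws)
        ess = np.exp(2 * logsumexp(logw) - logsumexp(2 * logw))
        assert ess > 100  # the oracle itself must be reliable
        assert ll_lap == pytest.approx(ll_mc, abs=0.5)


class TestCtcrw:
    def test_small_reversion_limit_is_integrated_brownian_motion(self):
        sigma, d = 0.7, 1.3
        T, Q = ctcrw_step(1e-10, sigma, np.array([d]))
        assert T[0, 0, 1] == pytest.approx(d, rel=1e-8)
        assert Q[0, 0, 0] == pytest.approx(sigma**2 * d**3 / 3, rel=1e-8)
        assert Q[0, 0, 1] == pytest.approx(sigma**2 * d**2 / 2, rel=1e-8)
        assert Q[0, 1, 1] == pytest.approx(sigma**2 * d, rel=1e-8)

    def test_branch_continuity(self):
        # the series and closed-form branches agree across the switch point
        Ta, Qa = ctcrw_step(0.99e-2, 0.5, np.array([1.0]))
        Tb, Qb = ctcrw_step(1.01e-2, 0.5, np.array([1.0]))
        # values at the two nearby betas differ by O(d_beta), so compare each
        # against a mid-beta linear interpolation
        Tm, Qm = ctcrw_step(1.0e-2, 0.5, np.array([1.0]))
        assert np.allclose(0.5 * (Qa + Qb), Qm, rtol=1e-6)
        assert np.allclose(0.5 * (Ta + Tb), Tm, rtol=1e-7)

    def test_gdcrw_likelihood_converges_to_ctcrw_under_refinement(
        self, persistent_params
    ):
        path, obs = make_track(persistent_params, n_obs=40, seed=10)
        ll_ct = ctcrw_loglik(0.9, np.exp(-2), obs, 0.1**2)
        gaps = []
        for spacing in (2.0, 1.0, 0.5, 0.25):
            grid = build_grid_aligned(obs.times, extra_spacing=spacing)
            sys = assemble_system(persistent_params, grid, obs, "aligned",
                                  noise_cov=0.1**2 * np.eye(2))
            gaps.append(abs(kalman_loglik(sys) - ll_ct))
        # decreasing trend: once the gap is near zero it fluctuates at the
        # scale of the remaining discretization error, so test the rank
        # correlation with the step size plus a tight endpoint
        from scipy.stats import spearmanr

        rho = spearmanr([2.0, 1.0, 0.5, 0.25], gaps).statistic
        assert rho > 0.7
        assert gaps[0] > gaps[-1]
        assert gaps[-1] < 0.15 * gaps[0]


class TestFitting:
    def test_recovery_within_reported_uncertainty(self, persistent_params):
        hits = 0
        for r in range(10):
            _, obs = make_track(persistent_params, n_obs=150, seed=100 + r)
            res = fit(obs, GridSpec("aligned", extra_spacing=1.0), ModelSpec())
            se = max(res.std_errors.get("gamma", np.nan), 1e-3)
            if abs(res.estimates["gamma"] - 0.9) <= 3 * se:
                hits += 1
        assert hits >= 8

    def test_invariance_under_time_and_space_shifts(self, persistent_params):
        _, obs = make_track(persistent_params, n_obs=80, seed=42)
        res1 = fit(obs, GridSpec("aligned"), ModelSpec(), smooth=False)
        shifted = ObservationSet(obs.times + 37.0, obs.coords + np.array([5.0, -3.0]))
        res2 = fit(shifted, GridSpec("aligned"), ModelSpec(), smooth=False)
        assert res1.loglik == pytest.approx(res2.loglik, abs=1e-4)
        assert res1.estimates["gamma"] == pytest.approx(
            res2.estimates["gamma"], abs=1e-5
        )

    def test_refit_is_deterministic(self, persistent_params):
        _, obs = make_track(persistent_params, n_obs=60, seed=43)
        a = fit(obs, GridSpec("aligned"), ModelSpec(), smooth=False)
        b = fit(obs, GridSpec("aligned"), ModelSpec(), smooth=False)
        assert a.loglik == b.loglik
        assert a.estimates == b.estimates

    def test_fit_reports_standard_errors_and_track(self, small_track):
        _, obs = small_track
        res = fit(obs, GridSpec("aligned"))
        assert res.track is not None and len(res.track) == len(res.grid)
        assert all(v >= 0 or np.isnan(v) for v in res.std_errors.values())
        assert {"gamma", "s11", "obs_sd"} <= set(res.estimates)

    def test_ctcrw_fit_recovers_parameters(self, persistent_params):
        gs = []
        for r in range(6):
            _, obs = make_track(persistent_params, n_obs=200, seed=300 + r)
            res = fit_ctcrw(obs, smooth=False)
            assert res.converged
            gs.append(res.estimates["gamma"])
        assert np.mean(gs) == pytest.approx(0.9, abs=0.03)

    def test_timescale_consistency_across_regular_grids(self, persistent_params):
        # fitting with step D and D/2 and correcting both gives compatible
        # per-time-unit estimates
        from gdcrw import correct_dcrw_params

        diffs = []
        for r in range(6):
            _, obs = make_track(persistent_params, n_obs=120, seed=500 + r)
            g = []
            for n_points in (120, 239):
                res = fit(
                    obs,
                    GridSpec("regular", n_points=n_points, unit_steps=True),
                    ModelSpec(),
                    smooth=False,
                )
                gc, _ = correct_dcrw_params(
                    res.estimates["gamma"], 0.0, res.details["step_scale"]
                )
                g.append(gc)
            diffs.append(g[0] - g[1])
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 0.02

    def test_student_t_fit_runs_and_converges(self, persistent_params):
        from gdcrw import default_argos_noise, simulate_observations
        from gdcrw.simulate import sample_observation_times, simulate_continuous

        rng = np.random.default_rng(77)
        times = sample_observation_times(40, seed=rng)
        path = simulate_continuous(persistent_params, times, substeps=40, seed=rng)
        noise = default_argos_noise()
        labels = np.array(["3", "B"], object)[rng.integers(0, 2, 40)]
        obs = simulate_observations(path, noise, labels, seed=rng)
        res = fit(obs, GridSpec("aligned"), ModelSpec(), noise)
        assert np.isfinite(res.loglik)
        assert {"sd_3", "df_3", "sd_B", "df_B"} <= set(res.estimates)
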