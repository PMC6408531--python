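"""Simulation-study drivers.

Three configurable experiments compare the irregular-step model (aligned
estimation points, optionally refined) against the exact continuous-time
model and against the regular-step model:

1. ``run_study1`` — tracks simulated from the zero-rotation continuous-time
   regime; fits the exact continuous-time model, the aligned irregular-step
   model, and aligned models with auxiliary points every ``k`` time units;
   compares autocorrelation estimates and smoothed-location accuracy.
2. ``run_study2`` — persistent (high autocorrelation, no rotation) and
   tortuous (low autocorrelation, rotation pi/3) regimes; fits the aligned
   model and the regular-step model at several grid sizes, recording raw
   per-step estimates and their time-scale-corrected values.
3. ``run_study3`` — a measurement-noise sweep comparing smoothed-location
   accuracy of aligned vs regular grids across noise levels.

All runs are pure functions of (config, master seed): replicate ``r`` uses
generators seeded by ``SeedSequence((master_seed, r, stream))`` so any cell
can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import FitResult, GridSpec, ModelSpec, fit, fit_ctcrw
from .kinematics import correct_dcrw_params
from .noise import NoiseModel
from .params import MovementParams
from .simulate import (
    StepMixtureConfig,
    sample_observation_times,
    simulate_continuous,
    simulate_observations,
)

__all__ = ["StudyConfig", "StudySummary", "run_study1", "run_study2", "run_study3"]

_QUANT_BANDS = ((0.1, 0.9), (0.2, 0.8), (0.3, 0.7), (0.4, 0.6))


def scenario_params(name: str) -> MovementParams:
    """True movement parameters of the named simulation scenario."""
    e2 = np.exp(-2.0)
    if name in ("ctcrw-comparison", "persistent"):
        return MovementParams.isotropic(0.9, e2)
    if name == "tortuous":
        return MovementParams.isotropic(0.6, e2, theta=np.pi / 3)
    raise ValueError(f"unknown scenario {name!r}")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration shared by the three studies.

    Defaults are the full-scale study conditions: 200 replicate tracks of
    250 irregularly timed observations (mixture mean gap about 2 time
    units), Gaussian measurement noise with standard deviation 0.1.
    """

    scenario: str = "ctcrw-comparison"
    n_replicates: int = 200
    n_obs: int = 250
    obs_sd: float = 0.1
    substeps: int = 200
    seed: int = 0
    step_cfg: StepMixtureConfig = field(default_factory=StepMixtureConfig)
    extra_spacings: tuple = ()  # study 1: auxiliary-point models, e.g. (8, 4, 2, 1)
    n_grid: tuple = (250,)  # study 2: estimated-location counts
    log_sd_grid: tuple = tuple(np.arange(-6.0, 2.5, 0.5))  # study 3

    def rng(self, *idx) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, *idx)))


@dataclass
class StudySummary:
    """Tidy result tables from one study run."""

    scenario: str
    params_table: pd.DataFrame
    ratio_table: pd.DataFrame | None = None
    n_failed: dict = field(default_factory=dict)


def _simulate_replicate(
    cfg: StudyConfig,
    params: MovementParams,
    r: int,
    level: tuple = (),
    obs_sd: float | None = None,
):
    times = sample_observation_times(cfg.n_obs, cfg.step_cfg, cfg.rng(*level, r, 0))
    path = simulate_continuous(
        params, times, substeps=cfg.substeps, seed=cfg.rng(*level, r, 1)
    )
    sd = cfg.obs_sd if obs_sd is None else obs_sd
    obs = simulate_observations(
        path, NoiseModel.gaussian(sd), seed=cfg.rng(*level, r, 2)
    )
    return path, obs


def _aligned_track_locs(res: FitResult) -> np.ndarray:
    """Smoothed locations at the observation times (aligned grid rows)."""
    tr = res.track
    return tr.loc[tr["aligned"], ["coord1", "coord2"]].to_numpy()


def _ok(res: FitResult) -> bool:
    return res.converged and np.isfinite(res.loglik)


def _ratio_stats(ratios: np.ndarray, model: str, extra: dict | None = None) -> dict:
    ratios = ratios[np.isfinite(ratios) & (ratios > 0)]
    logr = np.log(ratios)
    row = {
        "model": model,
        "n": ratios.size,
        "median_ratio": float(np.median(ratios)),
        "frac_lt_1": float(np.mean(ratios < 1.0)),
        "log_min": float(logr.min()) if logr.size else np.nan,
        "log_max": float(logr.max()) if logr.size else np.nan,
    }
    for lo, hi in _QUANT_BANDS:
        row[f"log_q{lo:.1f}"] = float(np.quantile(logr, lo))
        row[f"log_q{hi:.1f}"] = float(np.quantile(logr, hi))
    if extra:
        row.update(extra)
    return row


def run_study1(cfg: StudyConfig) -> StudySummary:
    """Exact continuous-time model vs the aligned irregular-step model."""
    if cfg.scenario != "ctcrw-comparison":
        raise ValueError("run_study1 requires scenario 'ctcrw-comparison'")
    params = scenario_params(cfg.scenario)
    models = ["ctcrw", "gdcrw"] + [f"gdcrw_{k:g}" for k in cfg.extra_spacings]
    gammas: dict[str, list] = {m: [] for m in models}
    dists: dict[str, dict[int, np.ndarray]] = {m: {} for m in models}
    failed = {m: 0 for m in models}
    noise = NoiseModel.gaussian(cfg.obs_sd, estimate=True)

    for r in range(cfg.n_replicates):
        path, obs = _simulate_replicate(cfg, params, r)
        truth = path.obs_locations
        results: dict[str, FitResult | None] = {}
        res = fit_ctcrw(obs, noise)
        results["ctcrw"] = res if _ok(res) else None
        res = fit(obs, GridSpec("aligned"), ModelSpec(), noise)
        results["gdcrw"] = res if _ok(res) else None
        for k in cfg.extra_spacings:
            res = fit(obs, GridSpec("aligned", extra_spacing=float(k)), ModelSpec(), noise)
            results[f"gdcrw_{k:g}"] = res if _ok(res) else None
        for m in models:
            if results[m] is None:
                failed[m] += 1
                continue
            gammas[m].append(results[m].estimates["gamma"])
            locs = _aligned_track_locs(results[m])
            dists[m][r] = np.linalg.norm(locs - truth, axis=1)

    rows = [
        {
            "model": m,
            "n_ok": len(gammas[m]),
            "mean_gamma": float(np.mean(gammas[m])) if gammas[m] else np.nan,
            "sd_gamma": float(np.std(gammas[m], ddof=1)) if len(gammas[m]) > 1 else np.nan,
        }
        for m in models
    ]
    ratio_rows = []
    d_ref = dists["ctcrw"]
    for m in models:
        if m == "ctcrw":
            continue
        # pool ratios over replicates where both fits succeeded
        shared = sorted(set(dists[m]) & set(d_ref))
        if not shared:
            continue
        ratios = np.concatenate([dists[m][r] / d_ref[r] for r in shared])
        ratio_rows.append(_ratio_stats(ratios, m))
    return StudySummary(
        cfg.scenario,
        pd.DataFrame(rows),
        pd.DataFrame(ratio_rows) if ratio_rows else None,
        failed,
    )


def run_study2(cfg: StudyConfig) -> StudySummary:
    """Aligned vs regular-step fits; raw and time-scale-corrected estimates."""
    if cfg.scenario not in ("persistent", "tortuous"):
        raise ValueError("run_study2 requires scenario 'persistent' or 'tortuous'")
    params = scenario_params(cfg.scenario)
    spec = ModelSpec(share_gamma=True, estimate_theta=True, share_s=True)
    noise = NoiseModel.gaussian(cfg.obs_sd, estimate=True)
    records = []
    failed: dict = {}

    for r in range(cfg.n_replicates):
        _, obs = _simulate_replicate(cfg, params, r)
        n_base = len(np.unique(obs.times))
        for N in cfg.n_grid:
            extra = max(int(N) - n_base, 0)
            res = fit(obs, GridSpec("aligned", extra_total=extra), spec, noise, smooth=False)
            if _ok(res):
                records.append(
                    {
                        "model": "gdcrw",
                        "n_grid": N,
                        "replicate": r,
                        "gamma": res.estimates["gamma"],
                        "theta": res.estimates["theta"],
                    }
                )
            else:
                failed[("gdcrw", N)] = failed.get(("gdcrw", N), 0) + 1
            res = fit(
                obs,
                GridSpec("regular", n_points=int(N), unit_steps=True),
                spec,
                noise,
                smooth=False,
            )
            if _ok(res):
                dt_tilde = res.details["step_scale"]
                g_raw = res.estimates["gamma"]
                # the likelihood is periodic in the per-step rotation
                t_raw = (res.estimates["theta"] + np.pi) % (2 * np.pi) - np.pi
                g_cor, t_cor = correct_dcrw_params(g_raw, t_raw, dt_tilde)
                records.append(
                    {
                        "model": "dcrw",
                        "n_grid": N,
                        "replicate": r,
                        "gamma": g_raw,
                        "theta": t_raw,
                        "gamma_corrected": g_cor,
                        "theta_corrected": t_cor,
                        "dt_tilde": dt_tilde,
                    }
                )
            else:
                failed[("dcrw", N)] = failed.get(("dcrw", N), 0) + 1

    df = pd.DataFrame(records)
    cols = [c for c in ("gamma", "theta", "gamma_corrected", "theta_corrected") if c in df]
    table = (
        df.groupby(["model", "n_grid"])[cols]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    table.columns = ["_".join(c).rstrip("_") for c in table.columns]
    return StudySummary(cfg.scenario, table, None, failed)


def run_study3(cfg: StudyConfig) -> StudySummary:
    """Smoothed-location accuracy across measurement-noise levels."""
    if cfg.scenario not in ("persistent", "tortuous"):
        raise ValueError("run_study3 requires scenario 'persistent' or 'tortuous'")
    params = scenario_params(cfg.scenario)
    spec = ModelSpec(share_gamma=True, estimate_theta=True, share_s=True)
    rows = []
    failed: dict = {}
    for li, log_sd in enumerate(cfg.log_sd_grid):
        ratios = []
        for r in range(cfg.n_replicates):
            path, obs = _simulate_replicate(
                cfg, params, r, level=(li,), obs_sd=float(np.exp(log_sd))
            )
            truth = path.obs_locations
            noise = NoiseModel.gaussian(float(np.exp(log_sd)), estimate=True)
            res_g = fit(obs, GridSpec("aligned"), spec, noise)
            res_d = fit(obs, GridSpec("regular", n_points=cfg.n_obs), spec, noise)
            if not (_ok(res_g) and _ok(res_d)):
                failed[log_sd] = failed.get(log_sd, 0) + 1
                continue
            d_g = np.linalg.norm(_aligned_track_locs(res_g) - truth, axis=1)
            tr = res_d.track
            interp = np.column_stack(
                [
                    np.interp(obs.times, tr["time"], tr[c])
                    for c in ("coord1", "coord2")
                ]
            )
            d_d = np.linalg.norm(interp - truth, axis=1)
            ratios.append(d_g / d_d)
        if ratios:
            rows.append(
                _ratio_stats(
                    np.concatenate(ratios), "gdcrw_vs_dcrw", {"log_sd": float(log_sd)}
                )
            )
    return StudySummary(cfg.scenario, pd.DataFrame(rows), None, failed)
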