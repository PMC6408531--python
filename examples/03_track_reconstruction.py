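"""Reconstruct a most-probable track and compare it with the raw fixes.

After fitting, the smoother combines all observations with the movement
model to produce location estimates (with uncertainty) that are typically
closer to the true path than the noisy fixes themselves.
"""

import numpy as np

from gdcrw import (
    GridSpec,
    ModelSpec,
    MovementParams,
    NoiseModel,
    fit,
    fit_ctcrw,
    sample_observation_times,
    simulate_continuous,
    simulate_observations,
)

true = MovementParams.isotropic(gamma=0.9, sigma=np.exp(-2))
times = sample_observation_times(250, seed=21)
path = simulate_continuous(true, times, seed=22)
obs = simulate_observations(path, NoiseModel.gaussian(0.1), seed=23)
truth = path.obs_locations

res = fit(obs, GridSpec("aligned"))
smoothed = res.track.loc[res.track["aligned"], ["coord1", "coord2"]].to_numpy()
err_raw = np.linalg.norm(obs.coords - truth, axis=1)
err_smooth = np.linalg.norm(smoothed - truth, axis=1)

res_ct = fit_ctcrw(obs)
err_ct = np.linalg.norm(
    res_ct.track[["coord1", "coord2"]].to_numpy() - truth, axis=1
)

print(f"mean distance to truth, raw fixes:        {err_raw.mean():.4f}")
print(f"mean distance to truth, smoothed (GDCRW): {err_smooth.mean():.4f}")
print(f"mean distance to truth, smoothed (CTCRW): {err_ct.mean():.4f}")
print(f"median GDCRW/CTCRW distance ratio: "
      f"{np.median(err_smooth / err_ct):.4f}")
print(
    "\nSmoothing cuts the raw location error by roughly a quarter here; the exact "
    "continuous-time model is marginally better than the discretized one "
    "(ratio slightly above 1) when it is the true data-generating model."
)
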