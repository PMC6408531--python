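"""Why regular-step estimates depend on the grid, and how to fix them.

The classic regular-step model estimates autocorrelation and rotation *per
step*, so the numbers change with the chosen step length.  The time-scale
correction gamma = gamma_tilde**(1/dt), theta = theta_tilde/dt maps them
back to a common per-time-unit scale.
"""

import numpy as np

from gdcrw import (
    GridSpec,
    ModelSpec,
    MovementParams,
    NoiseModel,
    correct_dcrw_params,
    fit,
    sample_observation_times,
    simulate_continuous,
    simulate_observations,
)

true = MovementParams.isotropic(gamma=0.6, sigma=np.exp(-2), theta=np.pi / 3)
times = sample_observation_times(250, seed=11)
path = simulate_continuous(true, times, seed=12)
obs = simulate_observations(path, NoiseModel.gaussian(0.1), seed=13)

spec = ModelSpec(estimate_theta=True)
print(f"true per-time-unit values: gamma=0.600 theta={np.pi/3:+.3f}\n")
print(f"{'N':>5} {'step':>6} {'raw gamma':>10} {'raw theta':>10} "
      f"{'corr gamma':>11} {'corr theta':>11}")
for n_points in (250, 750, 1250):
    res = fit(
        obs,
        GridSpec("regular", n_points=n_points, unit_steps=True),
        spec,
        smooth=False,
    )
    dt = res.details["step_scale"]
    g_raw = res.estimates["gamma"]
    t_raw = (res.estimates["theta"] + np.pi) % (2 * np.pi) - np.pi
    g, t = correct_dcrw_params(g_raw, t_raw, dt)
    print(f"{n_points:>5} {dt:>6.3f} {g_raw:>10.3f} {t_raw:>+10.3f} "
          f"{g:>11.3f} {t:>+11.3f}")
print(
    "\nRaw values drift with the grid size (finer steps -> higher gamma, "
    "smaller theta); the corrected columns stay near the truth and get "
    "closer as the discretization refines."
)
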