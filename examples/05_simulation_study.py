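"""A miniature replicate study comparing three model variants.

Runs a small version of the exact-vs-discretized comparison: tracks are
simulated from the continuous-time model and fitted with the exact
continuous-time filter, the aligned irregular-step model, and the aligned
model with auxiliary estimation points every 2 time units.
"""

from gdcrw import StudyConfig, run_study1

cfg = StudyConfig(
    scenario="ctcrw-comparison",
    n_replicates=10,
    n_obs=100,
    extra_spacings=(2,),
    seed=7,
)
summary = run_study1(cfg)
print(summary.params_table.to_string(index=False))
print()
print(
    summary.ratio_table[["model", "median_ratio", "frac_lt_1"]].to_string(index=False)
)
print(
    "\nmean_gamma should sit near the true 0.9 for all models; "
    "median_ratio > 1 means the discretized model's smoothed locations are "
    "slightly farther from the truth than the exact model's, and auxiliary "
    "points shrink that gap.  (Full-scale runs use 200 replicates of 250 "
    "observations.)"
)
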