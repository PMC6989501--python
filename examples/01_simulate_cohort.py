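"""Simulate a small two-arm longitudinal cohort with known ground truth.

The generator draws a global community composition, gives each subject a
personal offset and a daily-turnover SD (the "plasticity" trait), shifts
compositions between the pre-diet and ten-week windows, and emits multinomial
counts with lognormal library sizes and lane-specific taxon bias.
"""

import numpy as np

from plasticome import SimConfig, simulate_cohort

config = SimConfig(
    n_subjects_per_diet=6,
    n_taxa=60,
    days_per_window=3,
    depth_log_mean=np.log(5000),
    depth_log_sd=0.2,
    n_lanes=2,
    seed=7,
)
table, metadata, tree, taxonomy, truth = simulate_cohort(config)

print(f"count table: {table.shape[0]} samples x {table.shape[1]} taxa")
print(f"subjects: {metadata.n_subjects} "
      f"({(metadata.subjects.diet == 'low-carb').sum()} low-carb, "
      f"{(metadata.subjects.diet == 'low-fat').sum()} low-fat)")
print(f"median library size: {int(table.sum(axis=1).median())} reads")
print(f"success categories: {truth.success.value_counts().to_dict()}")
print(f"true per-subject daily turnover SD (first 4): "
      f"{truth.sigma_plasticity.iloc[:4].round(2).to_dict()}")
# Each subject contributes three consecutive daily samples per window; the
# turnover SD is the trait the plasticity statistics are built to estimate.
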