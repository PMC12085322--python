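"""Validate AHA trajectories against synthetic species presence.

Species presence is generated from AHA at the 1933 time step of a
patchwork landscape (districts develop at random times, half sealed and
half open at equal road density).  The permutation test flags clusters
enriched or depleted in presences; the GLM battery should place its best
AUC at 1933 — the planted time-lagged response — and prefer AHA over the
fixed-window HMD baseline.
"""

from ahascape import (
    align_quality_to_grid,
    build_analysis_grid,
    compute_aha_cube,
    compute_hmd,
    replication_config,
)
from ahascape.clustering import fit_ts_kmeans, trajectory_matrix
from ahascape.synth import fixture_spec, generate_landscape_series, generate_species_quality
from ahascape.validation import (
    BatterySpec,
    battery_to_dataframe,
    permutation_overlap_test,
    run_glm_battery,
)

spec, budgets, margin = fixture_spec("lag-recovery", seed=0)
stack = generate_landscape_series(spec)
grid = build_analysis_grid(stack, 250.0, margin_m=margin)
cube = compute_aha_cube(stack, replication_config(), grid, budgets)
quality = generate_species_quality(cube, spec, grid)
presence = align_quality_to_grid(quality, grid, stack.grid)
print(f"{len(grid)} focal points, presence rate {presence.presence.mean():.2f}")

labels = fit_ts_kmeans(trajectory_matrix(cube), k=4, n_init=10, seed=0).labels
perm = permutation_overlap_test(labels, presence["presence"].to_numpy(), seed=0)
print("\npermutation test (1000 shuffles, 99% confidence):")
print(perm.to_dataframe().to_string(index=False))

hmd = compute_hmd(stack, grid, [b.radius_m for b in cube.budgets])
battery = run_glm_battery(cube, hmd, presence, BatterySpec(seed=0))
df = battery_to_dataframe(battery)
print("\nmean AUC by metric and year (over scales and 25 subsample reps):")
print(df.groupby(["metric", "year"]).auc_mean.mean().unstack().round(3))
print("\nmean effect size by metric:",
      df.groupby("metric").effect_mean.mean().round(3).to_dict())
# The AHA column peaks at 1933 (the generating year) and beats HMD;
# effect sizes sit above 0.5 for AHA and below for HMD.
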