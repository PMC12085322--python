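# ahascape

Habitat availability for mobile generalist species in human-modified
landscapes, tracked over a century of land-cover change.

Landscape ecologists routinely summarize human pressure with fixed-shape
moving windows (e.g. the percentage of built-up cells within a radius).
Those metrics see barrier *density* but not barrier *configuration*: a
focal point ringed by roads has little reachable habitat no matter how
green the land beyond the ring is.  `ahascape` implements the **Amount
of Habitat Available (AHA)** metric, which takes the perspective of a
disperser moving through a resistant landscape, plus the downstream
analysis that links AHA trajectories to species presence: trajectory
clustering, a permutation test of cluster–presence overlap, and a
GLM/AUC/effect-size battery against the moving-window baseline (HMD).
A synthetic-landscape generator makes every stage testable end to end
without any map data.

## The metric

Each land-cover class gets a per-pixel crossing cost from the rank-cost
power law

```
C_i = (Rank_i / Rank_max)^x · C_max
```

with the replication defaults `x = 4`, `C_max = 500` per 10 m pixel,
ranks building = 3, road = 2.5, lake = 2, and fully permeable open land
at the base cost of 10 per pixel (1 cost unit per meter).  Roads and
buildings are pinned at 250 and 500.  Barriers
are semi-permeable: everything is finite, crossing is merely expensive.

From a focal cell, cost accumulates over the 8-connected grid
(orthogonal step = mean of the two cells' costs, diagonal step scaled by
√2) and is truncated at a dispersal budget *s* ∈ {250, 500, 1000, 2000,
4000}.  The reached cells form a resistance kernel of area `a_p`, and

```
AHA_p = a_p / (π R²),    R = frictionless range implied by the budget
```

so AHA is dimensionless in (0, 1] and comparable across budgets.  On
barrier-free land the kernel is the octagonal cost ball, which covers
2√2/π ≈ 0.90 of the Euclidean disc.

Computing AHA per focal point (250 m lattice), time step and budget
yields a `(points × years × budgets)` cube.  Trajectories are clustered
with K-Means (elbow-selected k), single-year "spatial" clusters are
aligned to them with the Kuhn–Munkres algorithm, and presence data are
tested by cluster-size-preserving permutation and by repeated
stratified-subsample logistic regressions (ROC-AUC, plus an effect size
defined as the inverse-logit of the standardized slope: 0.5 = no
association).

## A worked example

```python
import math, numpy as np
from ahascape import cost_distance_kernel
from ahascape.landscape_io import GridSpec
from ahascape.resistance import ResistanceSurface

n = 121
grid = GridSpec(0, n * 10, 10, n, n)
cost = np.full((n, n), 10.0)        # open land, 10 per pixel
walled = cost.copy(); walled[:, 70] = 500.0   # building wall 100 m east

for label, c in [("open land", cost), ("wall at +100 m", walled)]:
    surf = ResistanceSurface(grid=grid, cost=c)
    res = cost_distance_kernel(surf, (60, 60), 500.0)
    aha = res.a_p / (math.pi * res.budget.radius_m ** 2)
    print(label, res.n_cells, round(aha, 3))
```

prints

```
open land        7069 cells, AHA = 0.900
wall at +100 m   4489 cells, AHA = 0.572
```

Open land gives the frictionless octagonal value 0.90; crossing the
one-pixel wall would cost (10+500)/2 + (500+10)/2 = 510 > 500, so the
kernel is confined to the near side and AHA drops to 0.57.

The `examples/` scripts walk through each capability: resistance
surfaces, kernels, trajectory clustering on the three-archetype
landscape (cascading / high-stable / low-stable; the elbow picks k = 3
with adjusted Rand index 1.0 against the planted bands), species
validation on a time-lagged fixture (the GLM battery's AUC peaks at the
generating year 1933 and AHA out-predicts HMD), and the full pipeline
driver.  The same stages are available from the shell:

```
ahascape run --fixture tiny --seed 11 --outdir out/
ahascape simulate --scenario three-archetype --seed 0 --outdir fx/
ahascape aha --layer 1899=fx/landcover_1899.asc ... --out aha.csv
```

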