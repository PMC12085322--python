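# Methods

## Model

`ahascape` quantifies habitat availability for mobile generalist species
as the area reachable from a focal cell through a resistant landscape,
normalized by the frictionless maximum.  The model has three layers:

1. **Resistance.**  Categorical land cover (open / road / building /
   lake) maps to per-pixel crossing costs through the rank-cost power
   law `C_i = (Rank_i / Rank_max)^x · C_max`.  Ranks order classes by
   how strongly they impede movement; the contrast exponent
   `x ∈ {1, 2, 4, 8, 16}` controls how steeply cost falls below the top
   rank (default 4, under which the second rank costs roughly half the
   cap).  Defaults: building rank 3 of 3, road 2.5, lake 2,
   `C_max = 500` per 10 m pixel.  Fully permeable classes bypass the
   formula and take the base cost (10 per pixel = 1 per meter); running
   rank 1 through the power law would instead price open land at
   6.17/pixel and break the budget-to-meters correspondence.  The
   formula yields 241.13 for rank 2.5, while the conventionally used
   road value is 250; the shipped replication configuration therefore
   pins roads at 250 and buildings at 500 via explicit per-class
   overrides, with the formula value still available by clearing the
   overrides.  All costs are finite: barriers are semi-permeable.

2. **Kernels and AHA.**  From each focal cell, cost accumulates over
   the 8-connected grid: an orthogonal step costs the arithmetic mean of
   the two cells' per-pixel costs, a diagonal step the mean times √2.
   The focal cell costs nothing to occupy, even when it lies on a
   barrier, so AHA is defined everywhere.  Accumulation is truncated at
   a dispersal budget (defaults 250–4000 cost units, i.e. 250 m–4 km of
   open land); cells at exactly the budget are included (closed bound).
   With reached area `a_p`, `AHA = a_p / (π R²)` where `R` is the
   frictionless radius implied by the budget.  Areas are counted as
   cells × cell area; the polygon union of reached cells is provided for
   inspection and has provably identical area.  Engine:
   `skimage.graph.MCP_Geometric`, whose edge rule matches the statement
   above; the test suite holds an independently written Dijkstra and
   requires bit-for-bit agreement.  Each kernel runs on a square window
   of half-width `budget / min(cost)` cells around the focal cell, which
   contains every reachable cell, so windowing is exact, and focal
   points are computed independently (trivially parallelizable).

3. **Downstream analysis.**  AHA per focal point (regular 250 m
   lattice; each point at the centre of the fine cell nearest its block
   centroid), time step and budget forms a cube.  Trajectories
   (flattened year × budget vectors) are clustered by K-Means — under
   the Euclidean metric this equals multi-dimensional time-series
   K-Means — without feature scaling, since AHA is already normalized
   across budgets.  k comes from the within-cluster sum of squares curve
   via the maximum discrete second difference, with a manual override
   because visual elbow judgments cannot always be automated; a
   perfectly linear decline returns the smallest interior k with a
   warning.  Single-year clusters are aligned to trajectory clusters by
   the Kuhn–Munkres assignment maximizing shared points
   (`scipy.optimize.linear_sum_assignment` on the negated contingency
   table); with unequal cluster counts the surplus clusters remain
   unmatched and are reported.

## Validation statistics

* **Permutation test.**  Cluster labels are shuffled preserving cluster
  sizes (equivalently, presence flags are permuted) `n_perm = 1000`
  times.  A cluster *overlaps* presence when its observed count is
  strictly greater than in ≥ 99% of permutations, *deters* in the
  mirror case.  Strict inequalities against the empirical null make the
  test slightly conservative for small clusters (ties).

* **GLM battery.**  For each metric (AHA, HMD) × year × scale (each
  budget plus the joint "Allscales" model) × polynomial degree, presence
  is modelled by binomial GLM (IRLS via statsmodels) on predictors
  standardized within the fitted subsample.  Data are subsampled to 30%
  without replacement, stratified to 50% presences, 25 times; AUC is
  computed in-sample (no held-out split is defined for this analysis)
  and aggregated as mean/min/max.  Replicates with (quasi-)separation —
  a standardized slope beyond 15 in magnitude — are excluded with a
  warning.  Per-replicate seeds derive from the master seed through
  `numpy` SeedSequence spawn keys indexed by a global replicate counter.

* **Effect size.**  Reported as the inverse-logit of the standardized
  slope: exactly 0.5 at zero association, above 0.5 for positive, below
  for negative, approaching 0/1 monotonically.  This is the simplest
  transform with the conventional probability-scale reading of
  "change in occurrence probability per SD of predictor"; the quantity
  is not a formula taken from any single source and is documented here
  for that reason.

* **HMD baseline.**  Percentage of road/building cells within circular
  windows whose radii equal the dispersal distances, so AHA and HMD
  describe the same scales; windows clipped at the landscape edge use
  the clipped cell count as denominator.  Circularity matches the
  frictionless kernel's disc; the window shape is our choice where
  convention varies between square and circular.

## Synthetic landscapes

The generator emulates the structure the analysis assumes — binary
road/building rasters on a 10 m grid, road widths 10–50 m (1–5 cells),
strictly monotone infrastructure growth, static lakes, and a 100 m
species-quality raster of 3×3-neighbourhood presence counts (0–9) —
under three temporal archetypes per region: *cascading* (sparse narrow
dashed roads early; the same network sealed and widened after a
breakpoint year, collapsing AHA for configurational reasons while
density changes modestly), *saturating high* (near-pristine, flat) and
*saturating low* (the already-saturated version of the sealed network,
flat and low).  A *patchwork* scenario develops independent districts at
random time steps in one of two styles with equal road-cell density —
open-dashed versus sealed — which decorrelates AHA across years while
leaving density metrics largely uninformative; this is the setting used
to plant a time-lagged species response.

Species presence is Bernoulli per 100 m cell with
`logit p = α + β · z`, where `z` is the standardized AHA of the nearest
focal point at the lag year, and quality is the 3×3 presence count.  α
is calibrated so the *analysis-level* presence rate (a focal block is
present when any quality cell it touches is ≥ 1) hits the 20% target;
calibrating the raw cell rate instead would inflate block prevalence to
near saturation through the smoothing and block-max aggregation.

Fixture catalog (all text rasters, generated at run time):

| fixture | extent | timesteps | budgets | margin | purpose |
|---|---|---|---|---|---|
| `tiny` | 1 km² | 2 | 250, 500 | 0 | smoke/pipeline runs in seconds |
| `three-archetype` | 3.25 × 2.25 km | 4 | 250, 500 | 500 m | clustering recovery |
| `lag-recovery` | 9 × 9 km | 4 | 250, 500 | 0 | time-lag + AHA-vs-HMD battery |

Design notes.  Archetype bands are 750 m, commensurate with the 250 m
lattice so no focal block straddles a boundary; the static low band sits
between the two dynamic ones, buffering their temporal signals; the
500 m analysis margin excludes kernels clipped by the data edge (the
same reason production analyses exclude peripheral areas).  These
choices make the three planted trajectories nearly equidistant in
feature space, which is what lets an automated second-difference elbow
land on k = 3 reliably.  Patchwork districts are 750 m (3×3 focal
blocks) and the species link uses the 500-unit budget so the ±100 m
quality smoothing stays small relative to the kernel scale; the link
slope β = 4 was fixed by design simulation across generator seeds before
the corresponding tests were written.

What the generator does **not** emulate: cartographic artifacts of
digitized historical maps, curved/graded road geometry, urban-growth
realism, observation bias in species records, or spatial
autocorrelation of presences beyond what the AHA link induces.  Passing
tests therefore demonstrate that the pipeline recovers structure it is
designed to detect under its own assumptions — not that any particular
real landscape satisfies those assumptions.

## Numerical choices and degenerate inputs

* Budgets use a closed truncation (`≤`); frictionless AHA equals the
  octagonal/disc ratio 2√2/π ≈ 0.9003 up to cell quantization, and the
  acceptance band [0.85, 1.005] allows rasterization slack.
* Kernel costs are float64; the MCP engine and the oracle agree exactly
  on the tested grids because both accumulate identical left-to-right
  path sums.
* K-Means uses `n_init = 10` restarts; seeds are mandatory throughout
  and all tabular outputs are byte-reproducible for a given config.
* Empty clusters in the permutation test are valid (count 0); zero
  presences yield all-not-significant verdicts.
* Degenerate WCSS curves (under 3 points) are rejected; constant
  predictors and single-class AUC evaluations raise errors naming the
  problem.
* The 100 m → 250 m quality aggregation takes the MAX over intersecting
  coarse cells (area weighting ignored): the quality map is already a
  neighbourhood count, and max preserves any presence signal.  This is
  a package choice where convention is unstated.

## Problem sizes

The shipped fixtures run the full stack at desk scale: the acceptance
suite completes in about half a minute (kernel oracle on 200 grids up to
30×30, 50 monotonicity fixtures, the three-archetype clustering run, a
200-dataset permutation calibration at 1000 shuffles each, and one
lag-recovery battery over 1296 focal points × 4 years × 2 budgets × 25
subsample replicates).  Production-scale runs (10⁵+ focal points, 8
time steps, 5 budgets) are a matter of the same calls on larger rasters;
per-point independence makes the kernel stage embarrassingly parallel.

## Known limitations

* The elbow rule is a heuristic; real WCSS curves are rarely as clean
  as the planted fixture and the override exists precisely for that.
* In-sample AUC on balanced subsamples is optimistic relative to
  held-out evaluation; comparisons between metrics (AHA vs HMD) share
  the bias and remain meaningful.
* The effect-size transform compresses large slopes; it is meant for
  sign-and-magnitude reading near 0.5, not as a calibrated probability.
* No CRS handling or reprojection: all rasters must share one grid.
* Kernel costs assume isotropic movement; slope, wind or behavioral
  anisotropy would need a directed edge rule.
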