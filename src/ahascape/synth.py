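"""Synthetic landscape time series with controllable AHA trajectories.

The generator emulates the statistical structure the analysis assumes:
binary road/building rasters on a 10 m grid over an ordered series of
time steps, with monotone infrastructure growth (nothing is ever
demolished), static lakes, road widths of 10-50 m, and a coarse 100 m
species-quality raster whose presences are linked logistically to AHA
at a chosen historical time step.

Temporal trajectories are controlled per region through three
archetypes of human-modification impact:

* ``cascading`` — road networks are laid out early but with open gaps
  at the edges; after a breakpoint time step the gaps close, and AHA
  collapses for configurational reasons while barrier density changes
  only modestly.
* ``saturating_high`` — near-pristine land with a trickle of small
  building clusters; AHA stays high and flat.
* ``saturating_low`` — densely developed from the first time step;
  AHA starts low and stays low however much density is added.

A fourth ``patchwork`` scenario develops independent districts at
random time steps, which decorrelates the AHA cross-section between
years — the setting needed to demonstrate time-lagged species response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import convolve
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.special import expit

from .landscape_io import (
    DEFAULT_CLASS_CODES,
    AnalysisGrid,
    GridSpec,
    LandcoverStack,
    SpeciesQualityGrid,
    build_analysis_grid,
    write_ascii_grid,
    write_landcover_stack,
)

__all__ = [
    "ScenarioSpec",
    "generate_landscape_series",
    "generate_species_quality",
    "make_fixture_bundle",
    "FIXTURE_CATALOG",
]

ARCHETYPES = ("cascading", "saturating_high", "saturating_low", "patchwork")
DEFAULT_TIMESTEPS = [1899, 1918, 1933, 1959, 1970, 1978, 1992, 2012]


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic landscape series.

    Regions are vertical bands given as (archetype, x_frac0, x_frac1);
    the default splits the extent into the three trajectory archetypes.
    Road widths are drawn from 10-50 m (1-5 cells); infrastructure only
    ever grows; lakes are static rectangles in map-fraction coordinates.
    """

    width_m: float = 2400.0
    height_m: float = 2400.0
    cell_size: float = 10.0
    timesteps: list[int] = field(default_factory=lambda: list(DEFAULT_TIMESTEPS))
    # the static saturating_low band sits in the middle: its kernels stay
    # confined locally, so it buffers the two dynamic archetypes from
    # each other's temporal signal
    regions: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("cascading", 0.0, 1 / 3),
            ("saturating_low", 1 / 3, 2 / 3),
            ("saturating_high", 2 / 3, 1.0),
        ]
    )
    breakpoint_index: int = 2  # cascading regions close their road gaps here
    road_grid_spacing_m: float = 200.0
    lakes: list[tuple[float, float, float, float]] = field(default_factory=list)
    # patchwork scenario
    district_m: float = 400.0
    undeveloped_fraction: float = 0.35
    # species link
    species_lag_index: int = 1
    species_budget_index: int = 0
    species_beta: float = 1.5
    species_prevalence: float = 0.20
    species_cell_size: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for arch, a, b in self.regions:
            if arch not in ARCHETYPES:
                raise ValueError(f"unknown archetype {arch!r}")
            if not 0 <= a < b <= 1:
                raise ValueError(f"region bounds ({a}, {b}) invalid")
        for i, (_, a, b) in enumerate(self.regions[:-1]):
            if b > self.regions[i + 1][1] + 1e-9:
                raise ValueError("regions overlap inconsistently")
        if not 0 < self.species_prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


def _draw_road(
    mask: np.ndarray, orient: str, pos: int, lo: int, hi: int, width: int, dash: tuple[int, int] | None
) -> None:
    """Rasterize one axis-aligned road of ``width`` cells; ``dash``
    (on, off) leaves periodic gaps."""
    span = np.arange(lo, hi)
    if dash is not None:
        on, off = dash
        span = span[((span - lo) % (on + off)) < on]
    w0 = pos - width // 2
    sl = slice(max(w0, 0), min(w0 + width, mask.shape[0 if orient == "h" else 1]))
    if orient == "h":
        mask[sl, span.clip(0, mask.shape[1] - 1)] = True
    else:
        mask[span.clip(0, mask.shape[0] - 1), sl] = True


def _grid_roads(
    shape: tuple[int, int],
    cols: tuple[int, int],
    spacing: int,
    widths: np.ndarray,
    dash: tuple[int, int] | None,
) -> np.ndarray:
    """A rectangular lattice of roads inside a column band."""
    mask = np.zeros(shape, dtype=bool)
    c0, c1 = cols
    wi = 0
    for r in range(spacing // 2, shape[0], spacing):
        _draw_road(mask, "h", r, c0, c1, int(widths[wi % len(widths)]), dash)
        wi += 1
    for c in range(c0 + spacing // 2, c1, spacing):
        _draw_road(mask, "v", c, 0, shape[0], int(widths[wi % len(widths)]), dash)
        wi += 1
    return mask


def _building_blocks(
    shape: tuple[int, int],
    cols: tuple[int, int],
    n: int,
    rng: np.random.Generator,
    size_range: tuple[int, int] = (2, 5),
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    c0, c1 = cols
    for _ in range(n):
        h = int(rng.integers(*size_range))
        w = int(rng.integers(*size_range))
        r = int(rng.integers(0, max(shape[0] - h, 1)))
        c = int(rng.integers(c0, max(c1 - w, c0 + 1)))
        mask[r : r + h, c : c + w] = True
    return mask


def generate_landscape_series(spec: ScenarioSpec) -> LandcoverStack:
    """Coded land-cover rasters per time step, per the scenario regions.

    Road and building masks are cumulative (nested over time); lakes are
    identical at every time step.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_rows = int(round(spec.height_m / spec.cell_size))
    n_cols = int(round(spec.width_m / spec.cell_size))
    shape = (n_rows, n_cols)
    T = len(spec.timesteps)
    spacing = max(int(round(spec.road_grid_spacing_m / spec.cell_size)), 4)

    road = np.zeros((T,) + shape, dtype=bool)
    building = np.zeros((T,) + shape, dtype=bool)

    for arch, fa, fb in spec.regions:
        c0, c1 = int(fa * n_cols), int(fb * n_cols)
        widths = rng.integers(1, 6, size=8)  # 10-50 m at 10 m cells
        if arch == "cascading":
            # sparse narrow dashes early (roads barely impede movement);
            # after the break the same network is sealed and widened, so
            # crossing one road exceeds typical budgets
            wide = rng.integers(2, 6, size=8)
            dashed = _grid_roads(shape, (c0, c1), spacing, np.ones(8, dtype=int), dash=(3, 17))
            solid = _grid_roads(shape, (c0, c1), spacing, wide, dash=None)
            for it in range(T):
                road[it] |= solid if it >= spec.breakpoint_index else dashed
            for it in range(T):
                if it > 0:
                    building[it, :, c0:c1] |= building[it - 1, :, c0:c1]
                building[it] |= _building_blocks(shape, (c0, c1), 2 + it, rng)
        elif arch == "saturating_high":
            for it in range(T):
                if it > 0:
                    building[it, :, c0:c1] |= building[it - 1, :, c0:c1]
                building[it] |= _building_blocks(shape, (c0, c1), 1, rng, (2, 4))
        elif arch == "saturating_low":
            # already-saturated settlement density: the sealed road grid
            # is in place from the first time step
            wide = rng.integers(2, 6, size=8)
            base_roads = _grid_roads(shape, (c0, c1), spacing, wide, dash=None)
            base_bldg = _building_blocks(shape, (c0, c1), 12, rng)
            for it in range(T):
                road[it] |= base_roads
                if it > 0:
                    building[it, :, c0:c1] |= building[it - 1, :, c0:c1]
                building[it] |= base_bldg
                building[it] |= _building_blocks(shape, (c0, c1), 2, rng)
        elif arch == "patchwork":
            # districts develop at random time steps in one of two styles
            # with equal road-cell density but opposite configuration:
            # "open" grids are dashed (passable gaps), "sealed" grids are
            # solid.  Density-based metrics cannot tell them apart.
            d = int(round(spec.district_m / spec.cell_size))
            nbr, nbc = n_rows // d, max((c1 - c0) // d, 1)
            for bj in range(nbr):
                for bi in range(nbc):
                    if rng.random() < spec.undeveloped_fraction:
                        continue
                    t_dev = int(rng.integers(0, T))
                    sealed = rng.random() < 0.5
                    rr = slice(bj * d, (bj + 1) * d)
                    dcols = (c0 + bi * d, c0 + (bi + 1) * d)
                    sub = np.zeros(shape, dtype=bool)
                    if sealed:
                        g = _grid_roads(shape, dcols, max(spacing // 2, 4),
                                        np.ones(8, dtype=int), dash=None)
                    else:
                        g = _grid_roads(shape, dcols, max(spacing // 2, 4),
                                        np.full(8, 2, dtype=int), dash=(1, 1))
                    sub[rr, :] = g[rr, :]
                    bl = _building_blocks(shape, dcols, 4, rng, (2, 4))
                    bl[: bj * d] = False
                    bl[(bj + 1) * d :] = False
                    for it in range(t_dev, T):
                        road[it] |= sub
                        building[it] |= bl
    # enforce monotone nesting across the whole extent
    for it in range(1, T):
        road[it] |= road[it - 1]
        building[it] |= building[it - 1]

    lake = np.zeros(shape, dtype=bool)
    for fx0, fy0, fx1, fy1 in spec.lakes:
        lake[int(fy0 * n_rows) : int(fy1 * n_rows), int(fx0 * n_cols) : int(fx1 * n_cols)] = True

    grid = GridSpec(origin_x=0.0, origin_y=spec.height_m, cell_size=spec.cell_size,
                    n_rows=n_rows, n_cols=n_cols)
    layers: dict[int, np.ndarray] = {}
    for it, year in enumerate(spec.timesteps):
        layer = np.zeros(shape, dtype=np.int64)
        layer[road[it]] = 1
        layer[building[it]] = 2  # buildings trump roads where they touch
        layer[lake] = 3
        layers[year] = layer
    return LandcoverStack(grid=grid, timesteps=list(spec.timesteps), layers=layers)


def region_labels(spec: ScenarioSpec, grid: AnalysisGrid) -> np.ndarray:
    """Planted region index per focal point (for recovery tests)."""
    edges = np.array([fa for _, fa, _ in spec.regions] + [spec.regions[-1][2]])
    xf = grid.points["x"].to_numpy() / spec.width_m
    return np.clip(np.searchsorted(edges, xf, side="right") - 1, 0, len(spec.regions) - 1)


def generate_species_quality(
    aha_cube, spec: ScenarioSpec, analysis_grid: AnalysisGrid
) -> SpeciesQualityGrid:
    """Coarse landscape-quality raster linked logistically to AHA.

    Per 100 m cell a presence is drawn Bernoulli with
    ``logit p = alpha + beta * z`` where ``z`` is the standardized AHA of
    the nearest focal point at the lag time step, and ``alpha`` is
    calibrated so overall prevalence matches the target.  Quality is the
    3x3-neighbourhood presence count (0-9), mimicking how mobile-species
    observations are smoothed into a quality map.
    """
    T = aha_cube.values.shape[1]
    if not 0 <= spec.species_lag_index < T:
        raise ValueError(f"lag index {spec.species_lag_index} not in cube (T={T})")
    rng = np.random.default_rng(spec.seed + 7919)
    cs = spec.species_cell_size
    n_rows = int(round(spec.height_m / cs))
    n_cols = int(round(spec.width_m / cs))
    cy, cx = np.mgrid[0:n_rows, 0:n_cols]
    cell_x = (cx + 0.5) * cs
    cell_y = spec.height_m - (cy + 0.5) * cs
    pts = analysis_grid.points
    tree = cKDTree(np.column_stack([pts["x"], pts["y"]]))
    _, nearest = tree.query(np.column_stack([cell_x.ravel(), cell_y.ravel()]))
    aha = aha_cube.values[:, spec.species_lag_index, spec.species_budget_index]
    z_pts = (aha - aha.mean()) / max(aha.std(), 1e-12)
    z = z_pts[nearest]
    beta = spec.species_beta

    # Calibrate alpha so that the *analysis-level* presence rate (a focal
    # block is "present" when any quality cell it touches is >= 1, i.e.
    # any raw presence falls within one coarse cell of the block) matches
    # the target prevalence.  Calibrating the raw cell rate instead would
    # inflate block prevalence through the 3x3 smoothing and block-max
    # aggregation.
    spacing = analysis_grid.spacing
    influence: list[np.ndarray] = []
    for rec in pts.itertuples(index=False):
        bx0 = rec.block_i * spacing
        by0 = spec.height_m - rec.block_j * spacing  # top edge
        c0 = int(math.floor(bx0 / cs)) - 1
        c1 = int(math.ceil((bx0 + spacing) / cs)) + 1
        r0 = int(math.floor((spec.height_m - by0) / cs)) - 1
        r1 = int(math.ceil((spec.height_m - (by0 - spacing)) / cs)) + 1
        rr, cc = np.mgrid[max(r0, 0) : min(r1, n_rows), max(c0, 0) : min(c1, n_cols)]
        influence.append((rr * n_cols + cc).ravel())

    def block_prevalence(alpha: float) -> float:
        p = expit(alpha + beta * z)
        return float(np.mean([1.0 - np.prod(1.0 - p[idx]) for idx in influence]))

    alpha = brentq(lambda a: block_prevalence(a) - spec.species_prevalence, -30, 30)
    presence = (rng.random(z.size) < expit(alpha + beta * z)).astype(np.int64)
    presence = presence.reshape(n_rows, n_cols)
    quality = convolve(presence, np.ones((3, 3), dtype=np.int64), mode="constant", cval=0)
    grid = GridSpec(origin_x=0.0, origin_y=spec.height_m, cell_size=cs,
                    n_rows=n_rows, n_cols=n_cols)
    return SpeciesQualityGrid(grid=grid, quality=quality)


# ---------------------------------------------------------------------------
# Fixture catalog
# ---------------------------------------------------------------------------

def _tiny_spec(seed: int) -> ScenarioSpec:
    return ScenarioSpec(
        width_m=1000.0, height_m=1000.0,
        timesteps=[1899, 2012],
        regions=[("cascading", 0.0, 0.5), ("saturating_low", 0.5, 1.0)],
        breakpoint_index=1,
        lakes=[(0.05, 0.05, 0.2, 0.2)],
        species_lag_index=0,
        seed=seed,
    )


def _three_archetype_spec(seed: int) -> ScenarioSpec:
    # 750 m interior bands commensurate with the 250 m analysis lattice
    # (no focal block straddles a region boundary) plus a 500 m rim that
    # the analysis margin excludes, so no kernel is clipped by the edge
    return ScenarioSpec(
        width_m=3250.0, height_m=2250.0,
        timesteps=[1899, 1933, 1970, 2012],
        regions=[
            ("cascading", 0.0, 1250 / 3250),
            ("saturating_low", 1250 / 3250, 2000 / 3250),
            ("saturating_high", 2000 / 3250, 1.0),
        ],
        breakpoint_index=2,
        species_lag_index=1,
        seed=seed,
    )


def _lag_recovery_spec(seed: int) -> ScenarioSpec:
    # districts of 750 m (3x3 focal blocks) so most focal points sit
    # cleanly inside one district; the species link uses the smoother
    # 500-unit budget so the +-100 m quality smoothing stays small
    # relative to the kernel scale
    return ScenarioSpec(
        width_m=9000.0, height_m=9000.0,
        timesteps=[1899, 1933, 1970, 2012],
        regions=[("patchwork", 0.0, 1.0)],
        district_m=750.0,
        undeveloped_fraction=0.25,
        species_lag_index=1,
        species_budget_index=1,
        species_beta=4.0,
        seed=seed,
    )


FIXTURE_CATALOG = {
    "tiny": {"spec": _tiny_spec, "budgets": [250.0, 500.0], "margin": 0.0},
    "three-archetype": {"spec": _three_archetype_spec, "budgets": [250.0, 500.0], "margin": 500.0},
    "lag-recovery": {"spec": _lag_recovery_spec, "budgets": [250.0, 500.0], "margin": 0.0},
}


def fixture_spec(name: str, seed: int = 0) -> tuple[ScenarioSpec, list[float], float]:
    """Scenario, dispersal budgets and analysis-grid margin of one
    catalog fixture."""
    if name not in FIXTURE_CATALOG:
        raise ValueError(f"unknown fixture {name!r}; known: {sorted(FIXTURE_CATALOG)}")
    entry = FIXTURE_CATALOG[name]
    return entry["spec"](seed), list(entry["budgets"]), float(entry["margin"])


def make_fixture_bundle(name: str, directory: str | Path, seed: int = 0) -> Path:
    """Write one catalog fixture to disk: land-cover rasters, the species
    quality raster, a pipeline config, and summary CSVs."""
    from .kernels import compute_aha_cube
    from .resistance import replication_config

    spec, budgets, margin = fixture_spec(name, seed)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = generate_landscape_series(spec)
    paths = write_landcover_stack(stack, directory)
    grid = build_analysis_grid(stack, 250.0, margin_m=margin)
    cube = compute_aha_cube(stack, replication_config(), grid, budgets)
    quality = generate_species_quality(cube, spec, grid)
    write_ascii_grid(directory / "species_quality.asc", quality.grid, quality.quality)
    cube.to_dataframe(grid.points).to_csv(directory / "aha.csv", index=False)
    grid.points.to_csv(directory / "analysis_points.csv", index=False)
    config = {
        "fixture": name,
        "seed": seed,
        "cell_size": spec.cell_size,
        "grid_spacing": 250.0,
        "grid_margin": margin,
        "budgets": budgets,
        "landcover": {int(t): str(p.name) for t, p in paths.items()},
        "species_quality": "species_quality.asc",
        "class_codes": {int(k): v for k, v in DEFAULT_CLASS_CODES.items()},
    }
    with (directory / "config.yaml").open("w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return directory
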