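"""Raster and tabular I/O for the habitat-availability pipeline.

Rasters travel as ESRI ASCII grids (plain text, one header block and one
row of values per raster row).  Coordinates follow the usual geospatial
raster convention: the grid origin is the *top-left* corner of the
top-left cell, cells are indexed row-major from the top-left, and each
cell is the half-open square ``[x, x + cs) x (y - cs, y]`` in map units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "LandcoverStack",
    "SpeciesQualityGrid",
    "AnalysisGrid",
    "DEFAULT_CLASS_CODES",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_landcover_stack",
    "write_landcover_stack",
    "build_analysis_grid",
    "align_quality_to_grid",
]

#: Land-cover class coding used throughout: open/permeable land, roads,
#: buildings and (static) lakes.
DEFAULT_CLASS_CODES: dict[int, str] = {0: "open", 1: "road", 2: "building", 3: "lake"}


class AlignmentError(ValueError):
    """Rasters do not share a common grid."""


class ValidationError(ValueError):
    """Raster content violates the declared coding."""


class ConfigurationError(ValueError):
    """A configuration value is inconsistent with the data."""


class ExtentError(ValueError):
    """Two layers do not overlap spatially."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid.

    ``origin_x``/``origin_y`` give the map coordinates of the top-left
    corner of the top-left cell; ``cell_size`` is the square cell edge in
    meters.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_id: str = "local"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the centre of cell (row, col)."""
        cs = self.cell_size
        return (self.origin_x + (col + 0.5) * cs, self.origin_y - (row + 0.5) * cs)

    def cell_containing(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell whose half-open square contains (x, y)."""
        col = int(math.floor((x - self.origin_x) / self.cell_size))
        row = int(math.floor((self.origin_y - y) / self.cell_size))
        return row, col

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            math.isclose(self.origin_x, other.origin_x)
            and math.isclose(self.origin_y, other.origin_y)
            and math.isclose(self.cell_size, other.cell_size)
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
        )


@dataclass
class LandcoverStack:
    """Coded land-cover rasters on a shared fine grid, one per time step."""

    grid: GridSpec
    timesteps: list[int]
    layers: dict[int, np.ndarray]
    class_codes: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_CODES))

    def __post_init__(self) -> None:
        if list(self.layers.keys()) != list(self.timesteps):
            self.layers = {t: self.layers[t] for t in self.timesteps}
        shape = (self.grid.n_rows, self.grid.n_cols)
        for t, layer in self.layers.items():
            if layer.shape != shape:
                raise AlignmentError(
                    f"layer {t} has shape {layer.shape}, grid expects {shape}"
                )
            _validate_codes(layer, self.class_codes, label=str(t))

    def layer(self, timestep: int) -> np.ndarray:
        return self.layers[timestep]

    def barrier_mask(self, timestep: int) -> np.ndarray:
        """Boolean mask of road or building cells (human modification)."""
        codes = self.codes_for({"road", "building"})
        return np.isin(self.layers[timestep], codes)

    def codes_for(self, names: set[str]) -> list[int]:
        return [c for c, n in self.class_codes.items() if n in names]


@dataclass
class SpeciesQualityGrid:
    """Coarse raster of landscape-quality scores in 0..9.

    A score of 1 means an indicator species was recorded in one cell of
    the 3x3 neighbourhood, 9 means in all nine.
    """

    grid: GridSpec
    quality: np.ndarray

    def __post_init__(self) -> None:
        if self.quality.shape != (self.grid.n_rows, self.grid.n_cols):
            raise AlignmentError("quality raster shape does not match its grid")
        if self.quality.min() < 0 or self.quality.max() > 9:
            raise ValidationError("quality values must lie in 0..9")


@dataclass
class AnalysisGrid:
    """Regular lattice of focal points at which AHA/HMD are evaluated."""

    spacing: float
    points: pd.DataFrame  # columns: point_id, x, y, row, col, block_i, block_j

    def __len__(self) -> int:
        return len(self.points)


def _validate_codes(layer: np.ndarray, class_codes: Mapping[int, str], label: str) -> None:
    known = np.array(sorted(class_codes), dtype=layer.dtype)
    bad = ~np.isin(layer, known)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"layer {label}: unknown class code {layer[r, c]} at cell ({r}, {c})"
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | Path, *, crs_id: str = "local") -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid (.asc) into a (GridSpec, array) pair."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValidationError(f"{path}: missing ASCII grid header field {req!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = np.vstack(rows)
    if data.shape != (n_rows, n_cols):
        raise ValidationError(
            f"{path}: data shape {data.shape} does not match header ({n_rows}, {n_cols})"
        )
    cs = header["cellsize"]
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cs,
        cell_size=cs,
        n_rows=n_rows,
        n_cols=n_cols,
        crs_id=crs_id,
    )
    if np.all(data == np.round(data)):
        data = data.astype(np.int64)
    return grid, data


def write_ascii_grid(path: str | Path, grid: GridSpec, data: np.ndarray, *, nodata: int = -9999) -> None:
    """Write an array as an ESRI ASCII grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    is_int = np.issubdtype(data.dtype, np.integer)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x:.6f}\n")
        fh.write(f"yllcorner {grid.origin_y - grid.height:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        fmt = "%d" if is_int else "%.10g"
        np.savetxt(fh, data, fmt=fmt)


def read_landcover_stack(
    paths: Mapping[int, str | Path] | Sequence[tuple[int, str | Path]],
    class_codes: Mapping[int, str] | None = None,
) -> LandcoverStack:
    """Read per-timestep coded rasters into a validated stack.

    All files must share the grid geometry; codes outside ``class_codes``
    raise a validation error naming the offending cell.
    """
    if class_codes is None:
        class_codes = dict(DEFAULT_CLASS_CODES)
    items = list(paths.items()) if isinstance(paths, Mapping) else list(paths)
    if not items:
        raise ValidationError("no rasters given")
    grid0 = None
    layers: dict[int, np.ndarray] = {}
    for t, p in items:
        grid, data = read_ascii_grid(p)
        if grid0 is None:
            grid0 = grid
        elif not grid.same_geometry(grid0):
            raise AlignmentError(f"raster for timestep {t} does not share the stack grid")
        layers[t] = data.astype(np.int64)
    assert grid0 is not None
    return LandcoverStack(grid=grid0, timesteps=[t for t, _ in items], layers=layers)


def write_landcover_stack(stack: LandcoverStack, directory: str | Path, prefix: str = "landcover") -> dict[int, Path]:
    directory = Path(directory)
    out: dict[int, Path] = {}
    for t in stack.timesteps:
        p = directory / f"{prefix}_{t}.asc"
        write_ascii_grid(p, stack.grid, stack.layers[t])
        out[t] = p
    return out


# ---------------------------------------------------------------------------
# Analysis grid and species alignment
# ---------------------------------------------------------------------------

def build_analysis_grid(
    stack: LandcoverStack, spacing: float = 250.0, margin_m: float = 0.0
) -> AnalysisGrid:
    """Lay a regular lattice of focal points over the landscape.

    One point per ``spacing x spacing`` block fully inside the extent.
    Each point sits at the centre of the fine cell nearest the block
    centroid, so it can serve as a single-source kernel origin.

    ``margin_m`` drops blocks within that distance of the landscape
    boundary: kernels there would be clipped by the edge of the data,
    understating AHA (peripheral areas are commonly excluded from this
    kind of analysis for the same reason).
    """
    grid = stack.grid
    cs = grid.cell_size
    ratio = spacing / cs
    if spacing <= 0 or abs(ratio - round(ratio)) > 1e-9:
        raise ConfigurationError(
            f"spacing {spacing} must be a positive multiple of the cell size {cs}"
        )
    cells_per_block = int(round(ratio))
    nbx = grid.n_cols // cells_per_block
    nby = grid.n_rows // cells_per_block
    if nbx == 0 or nby == 0:
        raise ConfigurationError("spacing exceeds the landscape extent")
    records = []
    pid = 0
    for j in range(nby):  # block row, top to bottom
        for i in range(nbx):  # block col, left to right
            bx0, by0 = i * spacing, j * spacing
            if (
                bx0 < margin_m
                or by0 < margin_m
                or bx0 + spacing > grid.width - margin_m
                or by0 + spacing > grid.height - margin_m
            ):
                continue
            cx = grid.origin_x + (i + 0.5) * spacing
            cy = grid.origin_y - (j + 0.5) * spacing
            row, col = grid.cell_containing(cx, cy)
            x, y = grid.cell_center(row, col)
            records.append((pid, x, y, row, col, i, j))
            pid += 1
    if not records:
        raise ConfigurationError("margin leaves no analysis blocks inside the extent")
    points = pd.DataFrame(
        records, columns=["point_id", "x", "y", "row", "col", "block_i", "block_j"]
    )
    return AnalysisGrid(spacing=spacing, points=points)


def align_quality_to_grid(quality: SpeciesQualityGrid, grid: AnalysisGrid, stack_grid: GridSpec) -> pd.DataFrame:
    """Aggregate the coarse quality raster onto the analysis lattice.

    Each focal point's block takes the MAX quality over every coarse cell
    intersecting it (partial overlaps count).  Presence is max >= 1,
    high quality is max >= 5.
    """
    qg = quality.grid
    sp = grid.spacing
    # overlap check in map coordinates
    if (
        qg.origin_x >= stack_grid.origin_x + stack_grid.width
        or qg.origin_x + qg.width <= stack_grid.origin_x
        or qg.origin_y <= stack_grid.origin_y - stack_grid.height
        or qg.origin_y - qg.height >= stack_grid.origin_y
    ):
        raise ExtentError("quality raster does not overlap the analysis extent")
    rows = []
    eps = 1e-9
    for rec in grid.points.itertuples(index=False):
        bx0 = stack_grid.origin_x + rec.block_i * sp
        by0 = stack_grid.origin_y - rec.block_j * sp  # top edge
        # coarse column/row index ranges intersecting [bx0, bx0+sp) x (by0-sp, by0]
        c0 = int(math.floor((bx0 - qg.origin_x) / qg.cell_size + eps))
        c1 = int(math.ceil((bx0 + sp - qg.origin_x) / qg.cell_size - eps))
        r0 = int(math.floor((qg.origin_y - by0) / qg.cell_size + eps))
        r1 = int(math.ceil((qg.origin_y - (by0 - sp)) / qg.cell_size - eps))
        c0, c1 = max(c0, 0), min(c1, qg.n_cols)
        r0, r1 = max(r0, 0), min(r1, qg.n_rows)
        if r0 >= r1 or c0 >= c1:
            q = 0
        else:
            q = int(quality.quality[r0:r1, c0:c1].max())
        rows.append((rec.point_id, rec.x, rec.y, q, q >= 1, q >= 5))
    return pd.DataFrame(
        rows, columns=["point_id", "x", "y", "quality", "presence", "high_quality"]
    )
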