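"""Human Modification Density: the fixed-shape moving-window baseline.

HMD is the percentage of road or building cells inside a circular
window centred on each focal point, evaluated at radii matching the
dispersal budgets so AHA and HMD describe the same spatial scales.
Unlike the resistance kernel, the window shape never responds to the
landscape; HMD measures barrier *density* only, not configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape_io import AnalysisGrid, ConfigurationError, LandcoverStack

__all__ = ["HMDCube", "compute_hmd"]


@dataclass
class HMDCube:
    """HMD percentages indexed (focal point, timestep, window radius)."""

    values: np.ndarray  # shape (P, T, S), percent
    point_ids: np.ndarray
    timesteps: list[int]
    radii_m: list[float]

    def slice_year(self, timestep: int) -> np.ndarray:
        return self.values[:, self.timesteps.index(timestep), :]

    def to_dataframe(self, points: pd.DataFrame | None = None) -> pd.DataFrame:
        recs = []
        P, T, S = self.values.shape
        for ip in range(P):
            for it, year in enumerate(self.timesteps):
                for ib, r in enumerate(self.radii_m):
                    recs.append((int(self.point_ids[ip]), year, r, self.values[ip, it, ib]))
        df = pd.DataFrame(recs, columns=["point_id", "year", "radius_m", "hmd"])
        if points is not None:
            df = df.merge(points[["point_id", "x", "y"]], on="point_id", how="left")
            df = df[["point_id", "x", "y", "year", "radius_m", "hmd"]]
        return df


def _disc_offsets(radius_cells: float) -> tuple[np.ndarray, np.ndarray]:
    """Offsets of cells whose centre lies within the radius of the focal
    cell centre (focal included)."""
    n = int(math.floor(radius_cells))
    dr, dc = np.mgrid[-n : n + 1, -n : n + 1]
    inside = dr**2 + dc**2 <= radius_cells**2
    return dr[inside], dc[inside]


def compute_hmd(
    stack: LandcoverStack,
    grid: AnalysisGrid,
    radii_m: list[float],
) -> HMDCube:
    """Percent road/building within circular windows; windows clipped at
    the landscape edge use the clipped cell count as denominator."""
    cs = stack.grid.cell_size
    for r in radii_m:
        if r < cs:
            raise ConfigurationError(f"window radius {r} m is smaller than one {cs} m cell")
    offsets = [_disc_offsets(r / cs) for r in radii_m]
    n_rows, n_cols = stack.grid.n_rows, stack.grid.n_cols
    values = np.empty((len(grid), len(stack.timesteps), len(radii_m)), dtype=float)
    rows = grid.points["row"].to_numpy()
    cols = grid.points["col"].to_numpy()
    for it, t in enumerate(stack.timesteps):
        barrier = stack.barrier_mask(t)
        for ib, (dr, dc) in enumerate(offsets):
            for ip in range(len(grid)):
                rr = rows[ip] + dr
                cc = cols[ip] + dc
                ok = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
                n_in = int(ok.sum())
                n_bar = int(barrier[rr[ok], cc[ok]].sum())
                values[ip, it, ib] = 100.0 * n_bar / n_in
    return HMDCube(
        values=values,
        point_ids=grid.points["point_id"].to_numpy(),
        timesteps=list(stack.timesteps),
        radii_m=list(radii_m),
    )
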