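"""Landscape resistance surfaces from coded land cover.

Per-pixel traversal costs come from a rank-cost power law: each barrier
class holds a rank relative to the strongest barrier, and

    C_i = (Rank_i / Rank_max) ** x * C_max

with contrast exponent x in {1, 2, 4, 8, 16}.  Permeable classes (open
land, forest, wetland) bypass the formula and receive the base crossing
cost directly, preserving the budget-to-meters correspondence on
barrier-free land.  Barriers are semi-permeable: costs are finite
everywhere, so any cell can in principle be crossed at a price.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .landscape_io import GridSpec, LandcoverStack, ValidationError

__all__ = [
    "ResistanceConfig",
    "ResistanceSurface",
    "rank_to_cost",
    "build_resistance_surface",
    "replication_config",
]

#: Allowed contrast exponents; x = 4 gives the "average contrast" where the
#: second-ranked class costs roughly half the top-ranked one.
CONTRAST_EXPONENTS = (1, 2, 4, 8, 16)


def rank_to_cost(rank_i: float, rank_max: float, x: float, cmax_per_pixel: float) -> float:
    """Per-pixel crossing cost of a barrier class from its rank.

    ``(rank_i / rank_max) ** x * cmax_per_pixel`` — strictly increasing in
    the rank and equal to ``cmax_per_pixel`` at the top rank for every x.
    """
    if rank_i <= 0:
        raise ValueError(f"rank must be positive, got {rank_i}")
    if rank_i > rank_max:
        raise ValueError(f"rank {rank_i} exceeds rank_max {rank_max}")
    if x < 1:
        raise ValueError(f"contrast exponent must be >= 1, got {x}")
    return (rank_i / rank_max) ** x * cmax_per_pixel


@dataclass
class ResistanceConfig:
    """Parameters mapping land-cover classes to per-pixel crossing costs.

    ``ranks`` lists barrier classes only; classes in ``permeable`` get
    ``base_cost_per_pixel`` directly.  ``overrides`` pins explicit costs
    for selected classes, bypassing the formula (the shipped replication
    defaults pin road=250 and building=500, the conventional values).
    """

    ranks: dict[str, float] = field(default_factory=lambda: {"lake": 2.0, "road": 2.5, "building": 3.0})
    rank_max: float = 3.0
    contrast: int = 4
    cmax_per_pixel: float = 500.0
    base_cost_per_pixel: float = 10.0
    permeable: tuple[str, ...] = ("open",)
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.contrast not in CONTRAST_EXPONENTS:
            raise ValueError(f"contrast exponent must be one of {CONTRAST_EXPONENTS}")
        if self.cmax_per_pixel <= 0 or self.base_cost_per_pixel <= 0:
            raise ValueError("cmax_per_pixel and base_cost_per_pixel must be positive")
        for name, r in self.ranks.items():
            if not 0 < r <= self.rank_max:
                raise ValueError(f"rank for {name!r} must lie in (0, {self.rank_max}]")
        for name, c in self.overrides.items():
            if c <= 0:
                raise ValueError(f"override cost for {name!r} must be positive")

    def class_cost(self, name: str) -> float:
        """Per-pixel crossing cost of one named class."""
        if name in self.overrides:
            return float(self.overrides[name])
        if name in self.permeable:
            return float(self.base_cost_per_pixel)
        if name in self.ranks:
            return rank_to_cost(self.ranks[name], self.rank_max, self.contrast, self.cmax_per_pixel)
        raise ValidationError(f"class {name!r} has no rank, override or permeable entry")


def replication_config() -> ResistanceConfig:
    """The standard parameterisation: x=4, Cmax=500, base 10/pixel,
    with roads pinned at 250 and buildings at 500 cost units per pixel."""
    return ResistanceConfig(overrides={"road": 250.0, "building": 500.0})


@dataclass
class ResistanceSurface:
    """Per-pixel crossing-cost raster for one time step."""

    grid: GridSpec
    cost: np.ndarray
    timestep: int | None = None

    def __post_init__(self) -> None:
        if self.cost.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("cost raster shape does not match grid")
        if not np.isfinite(self.cost).all():
            raise ValueError("costs must be finite (barriers are semi-permeable)")
        if (self.cost <= 0).any():
            raise ValueError("costs must be positive")


def build_resistance_surface(
    layer: np.ndarray,
    config: ResistanceConfig,
    grid: GridSpec,
    class_codes: Mapping[int, str],
    timestep: int | None = None,
) -> ResistanceSurface:
    """Map a coded land-cover layer to a crossing-cost surface."""
    cost = np.empty(layer.shape, dtype=float)
    seen = np.zeros(layer.shape, dtype=bool)
    for code, name in class_codes.items():
        mask = layer == code
        if not mask.any():
            continue
        cost[mask] = config.class_cost(name)
        seen |= mask
    if not seen.all():
        r, c = np.argwhere(~seen)[0]
        raise ValidationError(f"unknown class code {layer[r, c]} at cell ({r}, {c})")
    return ResistanceSurface(grid=grid, cost=cost, timestep=timestep)


def resistance_series(stack: LandcoverStack, config: ResistanceConfig) -> dict[int, ResistanceSurface]:
    """One resistance surface per time step of the stack."""
    return {
        t: build_resistance_surface(stack.layers[t], config, stack.grid, stack.class_codes, timestep=t)
        for t in stack.timesteps
    }
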