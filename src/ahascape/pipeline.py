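"""End-to-end pipeline driver: resistance -> AHA -> HMD -> clustering ->
alignment -> permutation test -> GLM battery, with a machine-readable
run manifest.

Every stage writes plain CSV (and ASCII-grid rasters) so each can be
inspected or re-run independently; the driver only sequences operations
that the library modules already expose.  Reruns with an identical
config produce byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    align_cluster_labels,
    fit_spatial_kmeans,
    fit_ts_kmeans,
    select_k_elbow,
    trajectory_matrix,
    wcss_curve,
)
from .hmd import compute_hmd
from .kernels import DEFAULT_BUDGETS, compute_aha_cube
from .landscape_io import (
    align_quality_to_grid,
    build_analysis_grid,
    read_ascii_grid,
    read_landcover_stack,
    SpeciesQualityGrid,
)
from .resistance import ResistanceConfig, replication_config
from .synth import fixture_spec, generate_landscape_series, generate_species_quality
from .validation import BatterySpec, battery_to_dataframe, permutation_overlap_test, run_glm_battery

logger = logging.getLogger("ahascape")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, with the standard defaults."""

    outdir: Path
    seed: int
    fixture: str | None = None  # generate inputs from the fixture catalog
    landcover_paths: dict[int, Path] | None = None  # or read them from disk
    species_quality_path: Path | None = None
    resistance: ResistanceConfig = field(default_factory=replication_config)
    budgets: list[float] = field(default_factory=lambda: list(DEFAULT_BUDGETS))
    grid_spacing: float = 250.0
    grid_margin: float = 0.0
    cluster_k: int | None = None  # None: elbow over k_range
    k_range: list[int] = field(default_factory=lambda: list(range(1, 9)))
    n_init: int = 10
    n_perm: int = 1000
    confidence: float = 0.99
    fraction: float = 0.3
    balance: float = 0.5
    reps: int = 25
    degree: int = 1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        if self.fixture is None and not self.landcover_paths:
            raise ValueError("either a fixture name or land-cover paths are required")
        self.outdir = Path(self.outdir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written as
    ``manifest.json``).  Any stage failure aborts with the stage name."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}, "outputs": {}}
    stage = "inputs"
    try:
        if config.fixture is not None:
            spec, budgets, margin = fixture_spec(config.fixture, config.seed)
            config.budgets = budgets
            config.grid_margin = margin
            stack = generate_landscape_series(spec)
        else:
            spec = None
            stack = read_landcover_stack(config.landcover_paths)
        grid = build_analysis_grid(stack, config.grid_spacing, config.grid_margin)
        manifest["stages"][stage] = {"timesteps": stack.timesteps, "n_points": len(grid)}

        stage = "aha"
        cube = compute_aha_cube(stack, config.resistance, grid, config.budgets)
        aha_df = cube.to_dataframe(grid.points)
        _write(out / "aha.csv", aha_df, manifest)

        stage = "hmd"
        radii = [b.radius_m for b in cube.budgets]
        hmd = compute_hmd(stack, grid, radii)
        _write(out / "hmd.csv", hmd.to_dataframe(grid.points), manifest)

        stage = "species"
        if config.fixture is not None:
            quality = generate_species_quality(cube, spec, grid)
        else:
            qgrid, qdata = read_ascii_grid(config.species_quality_path)
            quality = SpeciesQualityGrid(grid=qgrid, quality=qdata)
        presence = align_quality_to_grid(quality, grid, stack.grid)
        _write(out / "presence.csv", presence, manifest)

        stage = "clustering"
        matrix = trajectory_matrix(cube)
        curve = wcss_curve(matrix, config.k_range, config.n_init, config.seed)
        _write(out / "wcss.csv", pd.DataFrame(curve, columns=["k", "wcss"]), manifest)
        k = select_k_elbow(curve, override=config.cluster_k)
        ts_model = fit_ts_kmeans(matrix, k, config.n_init, config.seed)
        sp_model = fit_spatial_kmeans(cube, stack.timesteps[-1], k, config.n_init, config.seed)
        labels = pd.DataFrame(
            {
                "point_id": grid.points["point_id"],
                "ts_cluster": ts_model.labels,
                "spatial_cluster": sp_model.labels,
            }
        )
        _write(out / "clusters.csv", labels, manifest)
        manifest["stages"][stage] = {"k": k, "ts_wcss": ts_model.wcss, "spatial_wcss": sp_model.wcss}

        stage = "alignment"
        alignment = align_cluster_labels(ts_model.labels, sp_model.labels)
        _write(out / "confusion.csv", alignment.confusion.reset_index(), manifest)
        manifest["stages"][stage] = {
            "mapping": {str(a): b for a, b in alignment.mapping.items()},
            "total_cost": alignment.total_cost,
            "unmatched": alignment.unmatched_a + alignment.unmatched_b,
        }

        stage = "permutation"
        perm = permutation_overlap_test(
            ts_model.labels,
            presence["presence"].to_numpy(),
            n_perm=config.n_perm,
            confidence=config.confidence,
            seed=config.seed,
        )
        _write(out / "permutation.csv", perm.to_dataframe(), manifest)

        stage = "glm"
        battery = run_glm_battery(
            cube,
            hmd,
            presence,
            BatterySpec(
                fraction=config.fraction,
                balance=config.balance,
                reps=config.reps,
                degree=config.degree,
                seed=config.seed,
            ),
        )
        _write(out / "glm_battery.csv", battery_to_dataframe(battery), manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d stage outputs", len(manifest["outputs"]))
    return manifest


def _write(path: Path, df: pd.DataFrame, manifest: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest["outputs"][path.name] = _sha256(path)
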