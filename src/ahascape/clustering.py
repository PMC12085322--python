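"""Trajectory and spatial clustering of AHA profiles.

Focal points with similar temporal change in AHA across all dispersal
budgets are grouped by K-Means on the flattened (timestep x budget)
feature vector — under the Euclidean metric this is identical to
multi-dimensional time-series K-Means.  No feature scaling is applied:
AHA is already normalized to be comparable across budgets.

The number of clusters is chosen from the within-cluster sum of squares
(WCSS) curve by the elbow rule (maximum discrete curvature), with a
manual override for the cases where visual judgment disagrees.  Two
labelings (e.g. trajectory clusters vs single-year "spatial" clusters)
are aligned by the Kuhn-Munkres assignment that maximizes shared points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .kernels import AHACube

__all__ = [
    "TrajectoryMatrix",
    "ClusterModel",
    "AlignmentResult",
    "trajectory_matrix",
    "fit_ts_kmeans",
    "fit_spatial_kmeans",
    "wcss_curve",
    "select_k_elbow",
    "align_cluster_labels",
]


@dataclass
class TrajectoryMatrix:
    """Per-point AHA trajectories flattened to (P, T*S)."""

    features: np.ndarray
    point_ids: np.ndarray
    n_timesteps: int
    n_budgets: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.features).all():
            raise ValueError("trajectory features contain non-finite values")
        if self.n_timesteps < 1 or self.n_budgets < 1:
            raise ValueError("need at least one timestep and one budget")


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    labels: np.ndarray
    wcss: float
    seed: int
    n_init: int


@dataclass
class AlignmentResult:
    """Optimal one-to-one correspondence between two labelings."""

    mapping: dict[int, int]
    unmatched_a: list[int]
    unmatched_b: list[int]
    confusion: pd.DataFrame
    total_cost: int  # points off the mapped diagonal


def trajectory_matrix(cube: AHACube) -> TrajectoryMatrix:
    P, T, S = cube.values.shape
    return TrajectoryMatrix(
        features=cube.values.reshape(P, T * S).copy(),
        point_ids=np.asarray(cube.point_ids),
        n_timesteps=T,
        n_budgets=S,
    )


def _fit_kmeans(features: np.ndarray, k: int, n_init: int, seed: int) -> ClusterModel:
    n_distinct = np.unique(features, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(features)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        labels=labels,
        wcss=float(km.inertia_),
        seed=seed,
        n_init=n_init,
    )


def fit_ts_kmeans(matrix: TrajectoryMatrix, k: int, n_init: int = 10, seed: int = 0) -> ClusterModel:
    """Best-of-``n_init`` K-Means on the flattened trajectories."""
    return _fit_kmeans(matrix.features, k, n_init, seed)


def fit_spatial_kmeans(
    cube: AHACube, timestep: int, k: int, n_init: int = 10, seed: int = 0
) -> ClusterModel:
    """K-Means on one time step's multi-budget AHA values only."""
    return _fit_kmeans(cube.slice_year(timestep), k, n_init, seed)


def wcss_curve(
    matrix: TrajectoryMatrix, k_range: list[int], n_init: int = 10, seed: int = 0
) -> list[tuple[int, float]]:
    if sorted(k_range) != list(k_range):
        raise ValueError("k_range must be ascending")
    return [(k, _fit_kmeans(matrix.features, k, n_init, seed).wcss) for k in k_range]


def select_k_elbow(curve: list[tuple[int, float]], override: int | None = None) -> int:
    """k at the elbow of the WCSS curve: maximum discrete second
    difference (curvature).  A perfectly linear decline has no elbow; the
    smallest interior k is returned with a warning.  ``override`` wins
    unconditionally for when the curve needs human judgment."""
    if override is not None:
        return override
    if len(curve) < 3:
        raise ValueError("need at least 3 (k, wcss) points to locate an elbow")
    ks = [k for k, _ in curve]
    ws = np.array([w for _, w in curve], dtype=float)
    curvature = ws[:-2] - 2 * ws[1:-1] + ws[2:]
    scale = max(ws.max() - ws.min(), 1e-12)
    if curvature.max() <= 1e-9 * scale:
        warnings.warn("no elbow: WCSS decline is (near-)linear; returning smallest interior k")
        return ks[1]
    return ks[1 + int(np.argmax(curvature))]


def align_cluster_labels(labels_a: np.ndarray, labels_b: np.ndarray) -> AlignmentResult:
    """Kuhn-Munkres matching of two labelings over the same points.

    Maximizes the shared-point overlap of matched pairs; with unequal
    cluster counts the surplus clusters of the larger side stay
    unmatched.  ``total_cost`` counts the points off the mapped diagonal.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must cover the same point set")
    confusion = pd.crosstab(pd.Series(labels_a, name="a"), pd.Series(labels_b, name="b"))
    C = confusion.to_numpy()
    ri, ci = linear_sum_assignment(-C)
    mapping = {int(confusion.index[i]): int(confusion.columns[j]) for i, j in zip(ri, ci)}
    overlap = int(C[ri, ci].sum())
    unmatched_a = [int(a) for a in confusion.index if a not in mapping]
    matched_b = set(mapping.values())
    unmatched_b = [int(b) for b in confusion.columns if b not in matched_b]
    return AlignmentResult(
        mapping=mapping,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        confusion=confusion,
        total_cost=int(labels_a.size - overlap),
    )
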