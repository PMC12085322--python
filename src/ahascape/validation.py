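"""Validation of habitat-availability patterns against species presence.

Two complementary checks:

* A permutation test asking whether each trajectory cluster holds more
  (or fewer) species presences than expected from a random reallocation
  of cluster labels that preserves cluster sizes.  A cluster "overlaps"
  presence if its observed count strictly exceeds the stated share
  (default 99%) of the permuted counts, and "deters" in the mirror case.

* A battery of binomial GLMs (logistic regressions) explaining presence
  from AHA or HMD, per year and dispersal scale plus a combined
  "Allscales" model, fitted on repeated class-balanced subsamples.  Each
  fit reports its ROC-AUC and an effect size: the inverse-logit of the
  standardized slope, i.e. the probability-scale association per one SD
  of the predictor — exactly 0.5 when there is no association, above 0.5
  for positive association, below for negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .hmd import HMDCube
from .kernels import AHACube

__all__ = [
    "PermutationResult",
    "GLMFit",
    "BatterySpec",
    "permutation_overlap_test",
    "stratified_subsample",
    "fit_binomial_glm",
    "compute_auc",
    "effect_size",
    "run_glm_battery",
]

Verdict = Literal["overlaps", "deters", "not_significant"]


@dataclass
class PermutationResult:
    clusters: np.ndarray
    observed: np.ndarray  # presence count per cluster
    null_counts: np.ndarray  # (n_perm, n_clusters)
    exceed_upper: np.ndarray  # fraction of null strictly below observed
    exceed_lower: np.ndarray  # fraction of null strictly above observed
    verdicts: list[Verdict]
    n_perm: int
    confidence: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.clusters,
                "observed": self.observed,
                "null_mean": self.null_counts.mean(axis=0),
                "frac_null_below": self.exceed_upper,
                "frac_null_above": self.exceed_lower,
                "verdict": self.verdicts,
            }
        )


def permutation_overlap_test(
    labels: np.ndarray,
    presence: np.ndarray,
    n_perm: int = 1000,
    confidence: float = 0.99,
    seed: int = 0,
) -> PermutationResult:
    """Cluster-size-preserving permutation test of presence enrichment.

    Shuffling the labels while keeping each cluster's size fixed is
    equivalent to permuting the presence flags; per permutation the
    presence count in each cluster is recorded.  Verdicts use strict
    inequalities against the empirical null: "overlaps" if the observed
    count is greater than in at least ``confidence`` of the
    permutations, "deters" in the mirror case.
    """
    labels = np.asarray(labels)
    presence = np.asarray(presence, dtype=bool)
    if labels.shape != presence.shape:
        raise ValueError("labels and presence must be aligned per point")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    clusters = np.unique(labels)
    k = clusters.size
    label_idx = np.searchsorted(clusters, labels)
    observed = np.bincount(label_idx, weights=presence, minlength=k).astype(int)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, k), dtype=int)
    p = presence.astype(float)
    for i in range(n_perm):
        null[i] = np.bincount(label_idx, weights=rng.permutation(p), minlength=k).astype(int)
    frac_below = (null < observed).mean(axis=0)
    frac_above = (null > observed).mean(axis=0)
    verdicts: list[Verdict] = []
    for j in range(k):
        if presence.sum() == 0:
            verdicts.append("not_significant")
        elif frac_below[j] >= confidence:
            verdicts.append("overlaps")
        elif frac_above[j] >= confidence:
            verdicts.append("deters")
        else:
            verdicts.append("not_significant")
    return PermutationResult(
        clusters=clusters,
        observed=observed,
        null_counts=null,
        exceed_upper=frac_below,
        exceed_lower=frac_above,
        verdicts=verdicts,
        n_perm=n_perm,
        confidence=confidence,
    )


def stratified_subsample(
    table: pd.DataFrame,
    fraction: float = 0.3,
    balance: float = 0.5,
    seed: int = 0,
    presence_col: str = "presence",
) -> pd.DataFrame:
    """Class-balanced subsample without replacement.

    Total size is ``floor(fraction * n)``; of it, ``balance`` presences
    and the rest absences.  Raises when either class cannot supply its
    share, naming the shortfall.
    """
    n = len(table)
    total = int(np.floor(fraction * n))
    n_pres = int(round(total * balance))
    n_abs = total - n_pres
    pres = table[table[presence_col].astype(bool)]
    absn = table[~table[presence_col].astype(bool)]
    if len(pres) < n_pres:
        raise ValueError(f"need {n_pres} presence rows, only {len(pres)} available")
    if len(absn) < n_abs:
        raise ValueError(f"need {n_abs} absence rows, only {len(absn)} available")
    rng = np.random.default_rng(seed)
    ip = rng.choice(len(pres), size=n_pres, replace=False)
    ia = rng.choice(len(absn), size=n_abs, replace=False)
    out = pd.concat([pres.iloc[np.sort(ip)], absn.iloc[np.sort(ia)]])
    return out.reset_index(drop=True)


@dataclass
class FittedGLM:
    """One fitted logistic regression on standardized predictors."""

    params: np.ndarray  # [intercept, slopes...]
    predictor_names: list[str]  # base predictors (squared terms implied by degree)
    means: np.ndarray
    sds: np.ndarray
    degree: int
    converged: bool
    separated: bool

    def design(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - self.means) / self.sds
        if self.degree == 2:
            Z = np.column_stack([Z, Z**2])
        return Z

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(self.params[0] + self.design(X) @ self.params[1:])


def fit_binomial_glm(
    y: np.ndarray, X: np.ndarray, predictor_names: list[str] | None = None, degree: int = 1
) -> FittedGLM:
    """Logistic regression (IRLS) of presence on standardized predictors.

    ``degree=2`` appends squared terms (of the already-standardized
    columns).  Perfect or quasi-perfect separation is flagged so callers
    can exclude the replicate from aggregates.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    names = predictor_names or [f"x{i}" for i in range(X.shape[1])]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = names[int(np.argmax(sds == 0))]
        raise ValueError(f"predictor {bad!r} is constant in the subsample")
    Z = (X - means) / sds
    if degree == 2:
        Z = np.column_stack([Z, Z**2])
    elif degree != 1:
        raise ValueError("degree must be 1 or 2")
    design = sm.add_constant(Z, has_constant="add")
    separated = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
            params = np.asarray(res.params)
            converged = bool(res.converged)
        except Exception:
            separated = True
            params = np.zeros(design.shape[1])
    if not separated and np.abs(params[1:]).max(initial=0.0) > 15:
        separated = True  # quasi-separation: standardized slopes diverging
    return FittedGLM(
        params=params,
        predictor_names=names,
        means=means,
        sds=sds,
        degree=degree,
        converged=converged,
        separated=separated,
    )


def compute_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based ROC-AUC of scores against presence (ties count half)."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: evaluation set holds a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def effect_size(fit: FittedGLM) -> np.ndarray:
    """Inverse-logit of each standardized slope: the probability-scale
    association per SD of predictor (0.5 = none)."""
    n_slopes = len(fit.predictor_names)
    return expit(fit.params[1 : 1 + n_slopes])


@dataclass
class BatterySpec:
    fraction: float = 0.3
    balance: float = 0.5
    reps: int = 25
    degree: int = 1
    full_data_fit: bool = False
    seed: int = 0


@dataclass
class GLMFit:
    """Aggregated replicate fits for one metric x year x scale cell."""

    metric: str
    year: int
    scale: str
    degree: int
    auc_mean: float
    auc_min: float
    auc_max: float
    effect_mean: np.ndarray
    n_replicates: int
    n_excluded: int
    full_data_auc: float | None = None
    replicate_aucs: list[float] = field(default_factory=list)


def _battery_seed(master: int, counter: int) -> int:
    # documented counter scheme: independent streams per replicate
    ss = np.random.SeedSequence(entropy=master, spawn_key=(counter,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_glm_battery(
    aha_cube: AHACube,
    hmd_cube: HMDCube | None,
    presence_table: pd.DataFrame,
    spec: BatterySpec = BatterySpec(),
) -> list[GLMFit]:
    """Fit the full metric x year x scale battery of presence models.

    For each AHA (and optionally HMD) predictor set — every dispersal
    scale per year plus the five-scale "Allscales" model — the data are
    stratified-subsampled ``reps`` times; each replicate is fitted,
    scored in-sample by AUC, and aggregated as mean/min/max.  Replicates
    flagged as separated are excluded from aggregates with a warning.
    """
    pres = presence_table.sort_values("point_id").reset_index(drop=True)
    y_all = pres["presence"].to_numpy(dtype=bool)
    results: list[GLMFit] = []
    counter = 0

    def scales_for(cube, kind: str) -> list[tuple[str, list[int]]]:
        S = cube.values.shape[2]
        per = [(str(_scale_label(cube, s, kind)), [s]) for s in range(S)]
        if S > 1:
            per.append(("Allscales", list(range(S))))
        return per

    jobs: list[tuple[str, object]] = [("AHA", aha_cube)]
    if hmd_cube is not None:
        jobs.append(("HMD", hmd_cube))
    for metric, cube in jobs:
        order = np.argsort(np.asarray(cube.point_ids))
        for it, year in enumerate(cube.timesteps):
            year_slice = cube.values[order][:, it, :]
            for scale_name, cols in scales_for(cube, metric):
                X = year_slice[:, cols]
                names = [f"{metric}_{scale_name}" ] if len(cols) == 1 else [
                    f"{metric}_{_scale_label(cube, s, metric)}" for s in cols
                ]
                aucs: list[float] = []
                effects: list[np.ndarray] = []
                excluded = 0
                for rep in range(spec.reps):
                    seed = _battery_seed(spec.seed, counter)
                    counter += 1
                    tbl = pd.DataFrame({"presence": y_all})
                    tbl = pd.concat([tbl, pd.DataFrame(X, columns=names)], axis=1)
                    try:
                        sub = stratified_subsample(tbl, spec.fraction, spec.balance, seed)
                    except ValueError:
                        excluded += 1
                        continue
                    Xs = sub[names].to_numpy()
                    ys = sub["presence"].to_numpy(dtype=int)
                    try:
                        fit = fit_binomial_glm(ys, Xs, names, degree=spec.degree)
                    except ValueError:
                        excluded += 1
                        continue
                    if fit.separated:
                        warnings.warn(
                            f"{metric} {year} {scale_name}: separated replicate excluded"
                        )
                        excluded += 1
                        continue
                    aucs.append(compute_auc(fit.predict(Xs), ys))
                    effects.append(effect_size(fit)[: len(names)])
                full_auc = None
                if spec.full_data_fit:
                    fit_full = fit_binomial_glm(y_all.astype(int), X, names, degree=spec.degree)
                    if not fit_full.separated:
                        full_auc = compute_auc(fit_full.predict(X), y_all.astype(int))
                results.append(
                    GLMFit(
                        metric=metric,
                        year=year,
                        scale=scale_name,
                        degree=spec.degree,
                        auc_mean=float(np.mean(aucs)) if aucs else float("nan"),
                        auc_min=float(np.min(aucs)) if aucs else float("nan"),
                        auc_max=float(np.max(aucs)) if aucs else float("nan"),
                        effect_mean=np.mean(effects, axis=0) if effects else np.array([]),
                        n_replicates=len(aucs),
                        n_excluded=excluded,
                        full_data_auc=full_auc,
                        replicate_aucs=aucs,
                    )
                )
    return results


def _scale_label(cube, s: int, kind: str) -> str:
    if hasattr(cube, "budgets"):
        return f"{int(cube.budgets[s].budget)}"
    return f"{int(cube.radii_m[s])}"


def battery_to_dataframe(results: list[GLMFit]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            (
                r.metric,
                r.year,
                r.scale,
                r.degree,
                r.auc_mean,
                r.auc_min,
                r.auc_max,
                float(r.effect_mean.mean()) if r.effect_mean.size else float("nan"),
                r.n_replicates,
                r.n_excluded,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metric",
            "year",
            "scale",
            "degree",
            "auc_mean",
            "auc_min",
            "auc_max",
            "effect_mean",
            "n_replicates",
            "n_excluded",
        ],
    )
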