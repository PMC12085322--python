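import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ahascape.clustering import (
    TrajectoryMatrix,
    align_cluster_labels,
    fit_spatial_kmeans,
    fit_ts_kmeans,
    select_k_elbow,
    wcss_curve,
)
from ahascape.kernels import AHACube, DispersalBudget


def planted_matrix(n_per=20, noise=0.01, seed=0):
    """Three archetype trajectories (T=4, S=2) with tiny jitter."""
    rng = np.random.default_rng(seed)
    high = np.tile([0.9, 0.8], 4)
    low = np.tile([0.15, 0.1], 4)
    casc = np.concatenate([np.tile([0.9, 0.8], 2), np.tile([0.15, 0.1], 2)])
    rows, labels = [], []
    for lbl, proto in enumerate([casc, high, low]):
        rows.append(proto + rng.normal(0, noise, size=(n_per, 8)))
        labels += [lbl] * n_per
    feats = np.vstack(rows)
    return TrajectoryMatrix(features=feats, point_ids=np.arange(len(feats)),
                            n_timesteps=4, n_budgets=2), np.array(labels)


def planted_cube(n_per=20, seed=0):
    m, labels = planted_matrix(n_per, seed=seed)
    values = m.features.reshape(-1, 4, 2)
    cube = AHACube(values=values, point_ids=m.point_ids, timesteps=[1899, 1933, 1970, 2012],
                   budgets=[DispersalBudget(250, 250), DispersalBudget(500, 500)])
    return cube, labels


class TestKMeans:
    def test_separates_planted_groups(self):
        m, truth = planted_matrix()
        model = fit_ts_kmeans(m, k=3, n_init=10, seed=0)
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_k1_closed_form(self):
        m, _ = planted_matrix()
        model = fit_ts_kmeans(m, k=1, n_init=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], m.features.mean(axis=0))
        assert model.wcss == pytest.approx(((m.features - m.features.mean(0)) ** 2).sum())

    def test_k_equals_distinct_rows_gives_zero_wcss(self):
        feats = np.array([[0.0, 0], [1, 1], [2, 2]])
        m = TrajectoryMatrix(features=feats, point_ids=np.arange(3), n_timesteps=1, n_budgets=2)
        assert fit_ts_kmeans(m, k=3, n_init=1, seed=0).wcss == pytest.approx(0.0)

    def test_k_beyond_distinct_rows_rejected(self):
        feats = np.zeros((5, 4))
        m = TrajectoryMatrix(features=feats, point_ids=np.arange(5), n_timesteps=2, n_budgets=2)
        with pytest.raises(ValueError):
            fit_ts_kmeans(m, k=2, n_init=1, seed=0)

    def test_spatial_clustering_on_single_year(self):
        cube, truth = planted_cube()
        model = fit_spatial_kmeans(cube, 2012, k=2, n_init=10, seed=0)
        # at 2012 cascading has collapsed onto the low group
        merged = np.where(truth == 0, 2, truth)
        assert adjusted_rand_score(merged, model.labels) == 1.0

    def test_same_seed_same_labels(self):
        cube, _ = planted_cube()
        a = fit_spatial_kmeans(cube, 1899, k=2, n_init=5, seed=7)
        b = fit_spatial_kmeans(cube, 1899, k=2, n_init=5, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_wcss_not_worse_than_single_init(self):
        m, _ = planted_matrix(noise=0.3)
        multi = fit_ts_kmeans(m, k=3, n_init=10, seed=0)
        single = fit_ts_kmeans(m, k=3, n_init=1, seed=0)
        assert multi.wcss <= single.wcss + 1e-9


class TestWCSSCurve:
    def test_elbow_on_planted_fixture(self):
        m, _ = planted_matrix()
        curve = wcss_curve(m, list(range(1, 7)), n_init=10, seed=0)
        ws = [w for _, w in curve]
        assert ws == sorted(ws, reverse=True)
        assert select_k_elbow(curve) == 3

    def test_single_k_total_dispersion(self):
        m, _ = planted_matrix()
        curve = wcss_curve(m, [1], n_init=1, seed=0)
        assert curve[0][1] == pytest.approx(((m.features - m.features.mean(0)) ** 2).sum())

    def test_duplicated_rows_double_wcss(self):
        m, _ = planted_matrix(noise=0.2)
        doubled = TrajectoryMatrix(
            features=np.vstack([m.features, m.features]),
            point_ids=np.arange(2 * len(m.features)),
            n_timesteps=4, n_budgets=2,
        )
        c1 = wcss_curve(m, [1, 2, 3], n_init=10, seed=0)
        c2 = wcss_curve(doubled, [1, 2, 3], n_init=10, seed=0)
        for (_, w1), (_, w2) in zip(c1, c2):
            assert w2 == pytest.approx(2 * w1, rel=1e-6)

    def test_linear_curve_warns_no_elbow(self):
        curve = [(1, 100.0), (2, 80.0), (3, 60.0), (4, 40.0)]
        with pytest.warns(UserWarning, match="no elbow"):
            assert select_k_elbow(curve) == 2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            select_k_elbow([(1, 10.0), (2, 5.0)])

    def test_override_wins(self):
        curve = [(1, 100.0), (2, 10.0), (3, 5.0), (4, 4.0)]
        assert select_k_elbow(curve, override=4) == 4


class TestAlignment:
    def test_identical_labelings(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        res = align_cluster_labels(labels, labels)
        assert res.mapping == {0: 0, 1: 1, 2: 2}
        assert res.total_cost == 0

    def test_recovers_permutation(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 5, size=200)
        perm = np.array([3, 0, 4, 1, 2])
        res = align_cluster_labels(labels, perm[labels])
        assert res.total_cost == 0
        assert res.mapping == {i: int(perm[i]) for i in range(5)}

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_matches_brute_force_minimum(self, k):
        rng = np.random.default_rng(k)
        for _ in range(10):
            a = rng.integers(0, k, size=60)
            b = rng.integers(0, k, size=60)
            res = align_cluster_labels(a, b)
            best = min(
                sum(np.sum((a == i) & (b == perm[i])) for i in range(k))
                for perm in itertools.permutations(range(k))
            )
            best_cost = len(a) - max(
                sum(np.sum((a == i) & (b == perm[i])) for i in range(k))
                for perm in itertools.permutations(range(k))
            )
            assert res.total_cost == best_cost

    def test_rectangular_reports_unmatched(self):
        a = np.repeat(np.arange(5), 10)
        b = np.repeat(np.arange(5), 10) % 3
        res = align_cluster_labels(a, b)
        assert len(res.mapping) == 3
        assert len(res.unmatched_a) == 2 and res.unmatched_b == []

    def test_confusion_marginals(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, size=100)
        b = rng.integers(0, 3, size=100)
        res = align_cluster_labels(a, b)
        np.testing.assert_array_equal(res.confusion.sum(axis=1).to_numpy(), np.bincount(a))
        np.testing.assert_array_equal(res.confusion.sum(axis=0).to_numpy(), np.bincount(b))
        assert res.confusion.to_numpy().sum() == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            align_cluster_labels(np.zeros(3, int), np.zeros(4, int))
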