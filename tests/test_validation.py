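import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from ahascape.hmd import HMDCube
from ahascape.kernels import AHACube, DispersalBudget
from ahascape.validation import (
    BatterySpec,
    compute_auc,
    effect_size,
    fit_binomial_glm,
    permutation_overlap_test,
    run_glm_battery,
    stratified_subsample,
)


class TestPermutationTest:
    def test_perfectly_enriched_cluster_overlaps(self):
        labels = np.repeat([0, 1, 2], 100)
        presence = labels == 1
        res = permutation_overlap_test(labels, presence, n_perm=500, seed=0)
        assert res.verdicts[1] == "overlaps"
        assert res.verdicts[0] == "deters" and res.verdicts[2] == "deters"

    def test_no_presence_everything_not_significant(self):
        labels = np.repeat([0, 1], 50)
        res = permutation_overlap_test(labels, np.zeros(100, bool), n_perm=200, seed=0)
        assert res.verdicts == ["not_significant", "not_significant"]

    def test_observed_counts_partition_presences(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 5, 300)
        presence = rng.random(300) < 0.3
        res = permutation_overlap_test(labels, presence, n_perm=200, seed=1)
        assert res.observed.sum() == presence.sum()
        assert res.null_counts.shape == (200, 5)
        assert (res.null_counts.sum(axis=1) == presence.sum()).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 4, 200)
        presence = rng.random(200) < 0.25
        a = permutation_overlap_test(labels, presence, n_perm=300, seed=9)
        b = permutation_overlap_test(labels, presence, n_perm=300, seed=9)
        np.testing.assert_array_equal(a.null_counts, b.null_counts)

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_overlap_test(np.zeros(10, int), np.zeros(10, bool), n_perm=50)


class TestStratifiedSubsample:
    def make_table(self, n=1000, prevalence=0.2, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "presence": rng.random(n) < prevalence,
            "x": rng.normal(size=n),
        })

    def test_balanced_counts(self):
        tbl = self.make_table()
        sub = stratified_subsample(tbl, fraction=0.3, balance=0.5, seed=0)
        assert len(sub) == 300
        assert sub.presence.sum() == 150

    def test_without_replacement(self):
        tbl = self.make_table(n=400)
        tbl["row_id"] = np.arange(400)
        sub = stratified_subsample(tbl, fraction=0.3, balance=0.5, seed=1)
        assert sub.row_id.is_unique

    def test_minority_shortfall_reported(self):
        tbl = self.make_table(n=100, prevalence=0.05)
        with pytest.raises(ValueError, match="presence"):
            stratified_subsample(tbl, fraction=0.8, balance=0.5, seed=0)

    def test_single_class_rejected(self):
        tbl = pd.DataFrame({"presence": [True] * 50, "x": np.zeros(50)})
        with pytest.raises(ValueError):
            stratified_subsample(tbl, fraction=0.5, balance=0.5, seed=0)

    def test_same_seed_identical(self):
        tbl = self.make_table()
        a = stratified_subsample(tbl, 0.3, 0.5, seed=3)
        b = stratified_subsample(tbl, 0.3, 0.5, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestGLM:
    def test_null_slope_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        y = rng.random(10_000) < 0.4  # independent of x
        fit = fit_binomial_glm(y, x, ["x"])
        assert abs(fit.params[1]) < 0.06

    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5000)
        y = rng.random(5000) < expit(0.2 + 1.0 * x)
        fit = fit_binomial_glm(y, x, ["x"])
        assert fit.params[1] == pytest.approx(1.0, abs=0.12)  # x already unit SD

    def test_allscales_has_five_slopes(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(500, 5))
        y = rng.random(500) < expit(X[:, 0])
        fit = fit_binomial_glm(y, X, [f"b{i}" for i in range(5)])
        assert len(fit.params) == 6 and len(effect_size(fit)) == 5

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_binomial_glm(np.array([0, 1, 0, 1]), np.ones(4), ["x"])

    def test_separation_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.astype(int)
        fit = fit_binomial_glm(y, x + np.random.default_rng(0).normal(0, 1e-3, 40), ["x"])
        assert fit.separated

    def test_degree_two_appends_squared_terms(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        y = rng.random(2000) < expit(1.0 - x**2)
        fit = fit_binomial_glm(y, x, ["x"], degree=2)
        assert len(fit.params) == 3
        assert fit.params[2] < -0.2  # negative curvature recovered


class TestAUC:
    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4000)
        assert compute_auc(rng.normal(size=4000), y) == pytest.approx(0.5, abs=0.03)

    def test_perfect_and_antiperfect(self):
        y = np.array([0, 0, 1, 1])
        assert compute_auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert compute_auc(np.array([0.9, 0.8, 0.2, 0.1]), y) == 0.0

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            compute_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    @given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    @settings(deadline=None, max_examples=30)
    def test_invariant_under_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 500)
        s = rng.normal(size=500) + y
        base = compute_auc(s, y)
        assert compute_auc(scale * s + shift, y) == pytest.approx(base)
        assert compute_auc(np.exp(s), y) == pytest.approx(base)


class TestEffectSize:
    def test_zero_slope_exactly_half(self):
        fit = fit_binomial_glm(
            np.array([0, 1] * 50), np.tile([1.0, -1.0, -1.0, 1.0], 25), ["x"]
        )
        fit.params[1] = 0.0
        assert effect_size(fit)[0] == 0.5

    def test_monotone_in_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=3000)
        effs = []
        for beta in (-1.0, 0.0, 1.0, 3.0):
            y = rng.random(3000) < expit(beta * x)
            effs.append(effect_size(fit_binomial_glm(y, x, ["x"]))[0])
        assert effs == sorted(effs)
        assert effs[0] < 0.5 < effs[2] < effs[3] < 1.0


def synthetic_cubes(n=200, seed=0):
    rng = np.random.default_rng(seed)
    aha_vals = rng.uniform(0.05, 0.95, size=(n, 2, 2))
    hmd_vals = rng.uniform(0, 100, size=(n, 2, 2))
    budgets = [DispersalBudget(250, 250), DispersalBudget(500, 500)]
    aha = AHACube(values=aha_vals, point_ids=np.arange(n), timesteps=[1899, 2012], budgets=budgets)
    hmd = HMDCube(values=hmd_vals, point_ids=np.arange(n), timesteps=[1899, 2012], radii_m=[250, 500])
    return aha, hmd


class TestBattery:
    def test_shape_contract(self):
        aha, hmd = synthetic_cubes()
        rng = np.random.default_rng(1)
        presence = pd.DataFrame({
            "point_id": np.arange(200),
            "presence": rng.random(200) < 0.4,
        })
        res = run_glm_battery(aha, None, presence, BatterySpec(reps=5, seed=0))
        # 2 years x (2 budgets + Allscales)
        assert len(res) == 6
        assert all(r.n_replicates + r.n_excluded == 5 for r in res)

    def test_reproducible_given_seed(self):
        aha, hmd = synthetic_cubes()
        rng = np.random.default_rng(2)
        presence = pd.DataFrame({"point_id": np.arange(200), "presence": rng.random(200) < 0.4})
        r1 = run_glm_battery(aha, hmd, presence, BatterySpec(reps=4, seed=5))
        r2 = run_glm_battery(aha, hmd, presence, BatterySpec(reps=4, seed=5))
        for a, b in zip(r1, r2):
            assert a.replicate_aucs == b.replicate_aucs
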