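"""Tests of PAIR SVM: feature selection, pairing, SVM, CV, weights, AUC."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from rehodc.containers import StatMap, default_affine
from rehodc.groupstats import ChangePanel, rm_anova_map
from rehodc.pairsvm import (CvResult, FeatureMask, PairDataset,
                            build_pair_dataset, feature_mask_from_f,
                            project_weights, split_half_cv, split_half_cv_clean,
                            train_linear_svm, voxel_auc)


def _gaussian_panel(n=31, shape=(6, 6, 4), effect=0.0, seed=0):
    """Change panel of pure-noise maps, optionally with a High-condition
    offset in a fixed corner region (a direct stand-in for pipeline output)."""
    rng = np.random.default_rng(seed)
    arr = rng.standard_normal((n, 3) + shape)
    region = np.zeros(shape, bool)
    region[:3, :3, :2] = True
    arr[:, 0, region] += effect  # condition order: High, Low, Sham
    mask = np.ones(shape, bool)
    return ChangePanel(data=arr, subjects=[f"s{i:02d}" for i in range(n)],
                       conditions=["High", "Low", "Sham"], mask=mask,
                       affine=default_affine(3.0, shape)), region


def _full_feature_mask(mask):
    return FeatureMask(indices=np.flatnonzero(mask.ravel()),
                       grid_shape=mask.shape, p_threshold=1.0)


class TestFeatureMask:
    def test_zero_f_map_selects_nothing(self):
        mask = np.ones((4, 4, 4), bool)
        fmap = StatMap(np.zeros(mask.shape), "F", df=(2, 60), mask=mask)
        with pytest.raises(ValueError):
            feature_mask_from_f(fmap, mask, 0.05)

    def test_unit_threshold_selects_all_mask_voxels(self):
        rng = np.random.default_rng(0)
        mask = rng.random((5, 5, 4)) > 0.5
        fmap = StatMap(np.where(mask, rng.random(mask.shape), 0), "F",
                       df=(2, 60), mask=mask)
        fm = feature_mask_from_f(fmap, mask, 1.0)
        assert len(fm) == int(mask.sum())

    def test_null_selection_fraction_near_alpha(self):
        """Independent null F values select ~5% of voxels at p < 0.05."""
        rng = np.random.default_rng(1)
        mask = np.ones((12, 12, 10), bool)
        f = stats.f.rvs(2, 60, size=mask.shape, random_state=rng)
        fmap = StatMap(f, "F", df=(2, 60), mask=mask)
        fm = feature_mask_from_f(fmap, mask, 0.05)
        frac = len(fm) / mask.sum()
        lo, hi = stats.binom.interval(0.999, mask.sum(), 0.05)
        assert lo <= len(fm) <= hi, frac


class TestPairDataset:
    def test_group_sizes_floor_and_ceil(self):
        panel, _ = _gaussian_panel(n=31)
        ds = build_pair_dataset(panel, ("High", "Sham"),
                                _full_feature_mask(panel.mask), seed=0)
        sizes = sorted([(ds.groups == "A").sum(), (ds.groups == "B").sum()])
        assert sizes == [15, 16]
        assert np.array_equal(ds.labels, np.where(ds.groups == "A", 1, -1))

    def test_contrast_reversal_negates_samples(self):
        panel, _ = _gaussian_panel(n=10)
        fm = _full_feature_mask(panel.mask)
        ds1 = build_pair_dataset(panel, ("High", "Sham"), fm, seed=4)
        ds2 = build_pair_dataset(panel, ("Sham", "High"), fm, seed=4)
        # same split (same seed): swapping the contrast flips every sample
        np.testing.assert_allclose(ds2.samples, -ds1.samples)

    def test_same_seed_same_assignment(self):
        panel, _ = _gaussian_panel(n=9)
        fm = _full_feature_mask(panel.mask)
        ds1 = build_pair_dataset(panel, ("High", "Low"), fm, seed=7)
        ds2 = build_pair_dataset(panel, ("High", "Low"), fm, seed=7)
        assert np.array_equal(ds1.groups, ds2.groups)

    def test_too_few_subjects_rejected(self):
        panel, _ = _gaussian_panel(n=3)
        with pytest.raises(ValueError):
            build_pair_dataset(panel, ("High", "Low"),
                               _full_feature_mask(panel.mask), seed=0)


def _dual_qp_svm(X, y, C):
    """Independent soft-margin dual solution via constrained optimization."""
    n = len(y)
    K = (X @ X.T) * np.outer(y, y)

    def neg_dual(a):
        return 0.5 * a @ K @ a - a.sum()

    cons = {"type": "eq", "fun": lambda a: a @ y}
    res = minimize(neg_dual, np.zeros(n), jac=lambda a: K @ a - 1.0,
                   bounds=[(0, C)] * n, constraints=[cons], method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-12})
    a = res.x
    w = (a * y) @ X
    sv = (a > 1e-8) & (a < C - 1e-8)
    b = np.mean(y[sv] - X[sv] @ w) if sv.any() else 0.0
    return w, b


class TestLinearSvm:
    def test_two_point_max_margin_closed_form(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, -1])
        model = train_linear_svm(X, y, C=1e6)
        np.testing.assert_allclose(model.weights, [1.0, 0.0], atol=1e-6)
        assert model.bias == pytest.approx(0.0, abs=1e-6)

    def test_duplicating_points_leaves_decision_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 3)) + np.array([2.0, 0, 0]) * rng.choice([1, -1], 8)[:, None]
        y = np.where(X[:, 0] > 0, 1, -1)
        m1 = train_linear_svm(X, y, C=10.0)
        m2 = train_linear_svm(np.vstack([X, X]), np.concatenate([y, y]), C=10.0)
        test = rng.standard_normal((20, 3))
        np.testing.assert_allclose(m1.decision(test), m2.decision(test), atol=1e-5)

    def test_agrees_with_qp_oracle_on_separable_set(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((10, 4))
        y = np.array([1] * 5 + [-1] * 5)
        X[:5, 0] += 3.0
        X[5:, 0] -= 3.0
        model = train_linear_svm(X, y, C=1.0, tol=1e-6)
        w, b = _dual_qp_svm(X, y, C=1.0)
        test = rng.standard_normal((30, 4))
        np.testing.assert_allclose(model.decision(test), test @ w + b, atol=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.ones((4, 2)), np.ones(4))


class TestSplitHalfCv:
    def test_strong_effect_classifies_above_95(self):
        panel, region = _gaussian_panel(n=16, effect=2.0, seed=1)
        fmap = rm_anova_map(panel)
        fm = feature_mask_from_f(fmap, panel.mask, 0.05)
        ds = build_pair_dataset(panel, ("High", "Sham"), fm, seed=1)
        cv = split_half_cv(ds, repeats=50, seed=1)
        assert cv.mean_accuracy >= 0.95

    def test_null_accuracy_near_chance_with_clean_selection(self):
        """Fold-internal feature selection keeps null accuracy at chance."""
        panel, _ = _gaussian_panel(n=16, effect=0.0, seed=2)
        cv = split_half_cv_clean(panel, ("High", "Sham"), repeats=30,
                                 seed=2, p_thresh=0.2)
        assert abs(cv.mean_accuracy - 0.5) <= 0.15

    def test_whole_cohort_selection_inflates_null_accuracy(self):
        """Selecting features from the full-cohort F map before CV is
        circular: even a null contrast classifies far above chance."""
        panel, _ = _gaussian_panel(n=16, effect=0.0, seed=2)
        fmap = rm_anova_map(panel)
        fm = feature_mask_from_f(fmap, panel.mask, 0.05)
        ds = build_pair_dataset(panel, ("Low", "Sham"), fm, seed=2)
        cv = split_half_cv(ds, repeats=30, seed=2)
        assert cv.mean_accuracy > 0.65

    def test_single_repeat_deterministic(self):
        panel, _ = _gaussian_panel(n=12, effect=1.0, seed=3)
        fm = _full_feature_mask(panel.mask)
        ds = build_pair_dataset(panel, ("High", "Low"), fm, seed=3)
        cv1 = split_half_cv(ds, repeats=1, seed=9)
        cv2 = split_half_cv(ds, repeats=1, seed=9)
        assert cv1.accuracies[0] == cv2.accuracies[0]
        np.testing.assert_array_equal(cv1.mean_weights, cv2.mean_weights)

    def test_pair_antisymmetry(self):
        """Negating all samples and labels preserves held-out correctness."""
        panel, _ = _gaussian_panel(n=12, effect=1.0, seed=4)
        fm = _full_feature_mask(panel.mask)
        ds = build_pair_dataset(panel, ("High", "Sham"), fm, seed=4)
        neg = PairDataset(samples=-ds.samples, labels=-ds.labels,
                          subjects=ds.subjects, groups=ds.groups,
                          contrast=ds.contrast, seed=ds.seed)
        cv = split_half_cv(ds, repeats=20, seed=5)
        cv_neg = split_half_cv(neg, repeats=20, seed=5)
        np.testing.assert_allclose(cv.accuracies, cv_neg.accuracies)

    def test_accuracy_nondecreasing_in_amplitude(self):
        accs = []
        for effect in (0.0, 0.8, 2.5):
            panel, _ = _gaussian_panel(n=14, effect=effect, seed=6)
            fm = _full_feature_mask(panel.mask)
            ds = build_pair_dataset(panel, ("High", "Sham"), fm, seed=6)
            accs.append(split_half_cv(ds, repeats=30, seed=6).mean_accuracy)
        assert accs[0] <= accs[1] <= accs[2]

    def test_feature_permutation_invariance(self):
        panel, _ = _gaussian_panel(n=12, effect=1.5, seed=7)
        fm = _full_feature_mask(panel.mask)
        ds = build_pair_dataset(panel, ("High", "Sham"), fm, seed=7)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.samples.shape[1])
        ds_perm = PairDataset(samples=ds.samples[:, perm], labels=ds.labels,
                              subjects=ds.subjects, groups=ds.groups,
                              contrast=ds.contrast, seed=ds.seed)
        cv = split_half_cv(ds, repeats=10, seed=8)
        cv_perm = split_half_cv(ds_perm, repeats=10, seed=8)
        np.testing.assert_allclose(cv.accuracies, cv_perm.accuracies, atol=1e-12)
        np.testing.assert_allclose(cv_perm.mean_weights, cv.mean_weights[perm],
                                   atol=1e-8)


class TestWeights:
    def test_zero_weights_give_zero_map(self):
        mask = np.ones((4, 4, 4), bool)
        fm = FeatureMask(indices=np.arange(10), grid_shape=(4, 4, 4),
                         p_threshold=0.05)
        cv = CvResult(accuracies=np.array([1.0]), mean_weights=np.zeros(10),
                      repeats=1, seed=0, C=1.0)
        out = project_weights(cv, fm, mask)
        assert not out.values.any()

    def test_projection_roundtrip(self):
        rng = np.random.default_rng(0)
        mask = np.ones((5, 5, 4), bool)
        idx = rng.choice(100, size=17, replace=False)
        fm = FeatureMask(indices=np.sort(idx), grid_shape=(5, 5, 4),
                         p_threshold=0.05)
        w = rng.standard_normal(17)
        cv = CvResult(accuracies=np.array([0.8]), mean_weights=w, repeats=1,
                      seed=0, C=1.0)
        out = project_weights(cv, fm, mask)
        np.testing.assert_allclose(out.values.ravel()[fm.indices], w)

    def test_strong_signal_weights_enriched_in_truth_region(self):
        panel, region = _gaussian_panel(n=20, effect=2.0, seed=9)
        fm = _full_feature_mask(panel.mask)
        ds = build_pair_dataset(panel, ("High", "Sham"), fm, seed=9)
        cv = split_half_cv(ds, repeats=20, seed=9)
        wmap = project_weights(cv, fm, panel.mask)
        absw = np.abs(wmap.values.ravel()[fm.indices])
        top = fm.indices[absw >= np.quantile(absw, 0.9)]
        truth_idx = set(np.flatnonzero(region.ravel()))
        overlap = len(truth_idx & set(top))
        n_truth, n_feat = len(truth_idx), len(fm)
        p = stats.hypergeom.sf(overlap - 1, n_feat, n_truth, len(top))
        assert p < 0.01

    def test_length_mismatch_rejected(self):
        fm = FeatureMask(indices=np.arange(5), grid_shape=(4, 4, 4),
                         p_threshold=0.05)
        cv = CvResult(accuracies=np.array([1.0]), mean_weights=np.zeros(7),
                      repeats=1, seed=0, C=1.0)
        with pytest.raises(ValueError):
            project_weights(cv, fm, np.ones((4, 4, 4), bool))


class TestVoxelAuc:
    def test_complete_separation_gives_one(self):
        assert voxel_auc([5.0, 6.0, 7.0], [1.0, 2.0]) == 1.0

    def test_identical_lists_give_half(self):
        assert voxel_auc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.5

    def test_pair_enumeration_example(self):
        """A=(3,1), B=(2,0): 3 of 4 concordant pairs -> AUC = 0.75."""
        assert voxel_auc([3.0, 1.0], [2.0, 0.0]) == 0.75

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 6, size=7).astype(float)  # ties likely
            b = rng.integers(0, 6, size=5).astype(float)
            pairs = [(1.0 if x > y else 0.5 if x == y else 0.0)
                     for x in a for y in b]
            assert voxel_auc(a, b) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            voxel_auc([], [1.0])

    def test_single_voxel_auc_below_multivariate_accuracy(self):
        """On a strong-signal cohort the multivariate split-half accuracy
        dominates the best single-voxel AUC-as-accuracy."""
        panel, region = _gaussian_panel(n=20, effect=1.0, seed=10)
        fmap = rm_anova_map(panel)
        fm = feature_mask_from_f(fmap, panel.mask, 0.05)
        ds = build_pair_dataset(panel, ("High", "Sham"), fm, seed=10)
        acc = split_half_cv(ds, repeats=30, seed=10).mean_accuracy
        vals = np.where(panel.mask, fmap.values, -np.inf)
        peak = np.unravel_index(int(np.argmax(vals)), vals.shape)
        a = panel.condition_values("High")[:, peak[0], peak[1], peak[2]]
        b = panel.condition_values("Sham")[:, peak[0], peak[1], peak[2]]
        assert voxel_auc(a, b) <= acc + 1e-9
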