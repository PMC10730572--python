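"""Feature screening, mRMR, SMOTE, SFS, classifiers, CV machinery, metrics."""

import numpy as np
import pytest

from qusnac.classify import (
    ClassifierSpec,
    SelectionSpec,
    compute_metrics,
    fit_predict,
    holdout_cv,
    mrmr_select,
    nested_loo_cv,
    pooled_group_mean,
    screen_features,
    sfs_select,
    smote_augment,
    smote_balance,
    train_pipeline,
)


def make_labels(n1, n0):
    return np.array(["NR"] * n1 + ["R"] * n0)


class TestScreening:
    def test_null_features_give_uniform_pvalues(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((400, 200))
        y = make_labels(120, 280)
        p = screen_features(X, y)
        # Kolmogorov-Smirnov distance of p-values from U(0,1)
        from scipy.stats import kstest

        assert kstest(p, "uniform").pvalue > 0.01

    def test_large_effect_detected(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((130, 5))
        y = make_labels(30, 100)
        X[:30, 2] += 2.0
        p = screen_features(X, y)
        assert p[2] < 1e-6
        assert np.argmin(p) == 2

    def test_constant_feature_flagged(self):
        X = np.ones((20, 2))
        X[:, 1] = np.random.default_rng(0).normal(size=20)
        p = screen_features(X, make_labels(8, 12))
        assert np.isnan(p[0]) and np.isfinite(p[1])

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            screen_features(np.ones((3, 2)), np.array(["NR", "R", "R"]))


class TestMrmr:
    def test_label_copy_selected_first(self):
        """A feature deterministically equal to the label maximizes MI."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 20))
        y = make_labels(40, 60)
        X[:, 7] = (y == "NR") * 1.0
        order = mrmr_select(X, y, top=5)
        assert order[0] == 7

    def test_duplicate_informative_feature_penalized(self):
        """An exact copy of the already-selected informative feature ranks
        below an independent weakly-informative feature."""
        rng = np.random.default_rng(3)
        n = 400
        y = make_labels(150, 250)
        yb = (y == "NR").astype(float)
        strong = yb + 0.05 * rng.standard_normal(n)
        weak = yb + 3.0 * rng.standard_normal(n)
        noise = rng.standard_normal((n, 2))
        X = np.column_stack([strong, strong.copy(), weak, noise])
        order = mrmr_select(X, y, top=4)
        assert order[0] == 0
        assert order.index(2) < order.index(1)  # weak beats the duplicate

    def test_top_zero_empty(self):
        assert mrmr_select(np.ones((10, 3)), make_labels(4, 6), top=0) == []

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mrmr_select(np.ones((5, 2)), np.array(["R"] * 5))


class TestSmote:
    def test_identical_minority_points_collapse(self):
        minority = np.ones((2, 3))
        synth = smote_balance(minority, 5, rng=np.random.default_rng(0))
        np.testing.assert_allclose(synth, 1.0)

    def test_exact_parity_and_originals_untouched(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 4))
        y = make_labels(10, 40)
        Xb, yb = smote_augment(X, y, rng=rng)
        assert (yb == 1).sum() == (yb == 0).sum() == 40
        np.testing.assert_array_equal(Xb[:50], X)

    def test_synthetic_points_on_minority_segments(self):
        """Every synthetic row lies on a segment between two minority rows."""
        rng = np.random.default_rng(2)
        minority = rng.standard_normal((12, 3))
        synth = smote_balance(minority, 40, k=5, rng=rng)
        for s in synth:
            on_segment = False
            for i in range(12):
                for j in range(12):
                    if i == j:
                        continue
                    ab = minority[j] - minority[i]
                    denom = ab @ ab
                    u = ((s - minority[i]) @ ab) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(minority[i] + u * ab, s, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_single_minority_row_rejected(self):
        with pytest.raises(ValueError):
            smote_balance(np.ones((1, 2)), 3)


class TestSfs:
    def test_perfect_feature_selected_alone(self):
        """One feature separates the classes; SFS stops after selecting it."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 8))
        y = make_labels(30, 30)
        X[:30, 5] += 10.0
        sel = sfs_select(X, y, ClassifierSpec(kind="KNN"), rng=np.random.default_rng(0))
        assert sel == [5]

    def test_max_zero_empty(self):
        X = np.random.default_rng(0).standard_normal((20, 4))
        sel = sfs_select(X, make_labels(10, 10), ClassifierSpec(kind="KNN"), max_features=0)
        assert sel == []

    def test_never_exceeds_ten(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 30))
        y = make_labels(30, 30)
        sel = sfs_select(X, y, ClassifierSpec(kind="KNN"), rng=np.random.default_rng(1))
        assert len(sel) <= 10


class TestFitPredict:
    def test_knn_nearest_self(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [0.1, 0.1], [4.9, 5.1]])
        y = np.array(["R", "NR", "R", "NR"])
        spec = ClassifierSpec(kind="KNN", knn_k_grid=(1,))
        pred, scores = fit_predict(spec, X, y, X)
        np.testing.assert_array_equal(pred, (y == "NR").astype(int))

    @pytest.mark.parametrize("kind", ["KNN", "SVM-RBF"])
    def test_separable_blobs(self, kind):
        rng = np.random.default_rng(5)
        Xtr = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(4, 1, (40, 3))])
        ytr = make_labels(40, 40)
        Xte = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(4, 1, (20, 3))])
        yte = (make_labels(20, 20) == "NR").astype(int)
        pred, scores = fit_predict(ClassifierSpec(kind=kind), Xtr, ytr, Xte, rng=np.random.default_rng(0))
        assert (pred == yte).mean() >= 0.95
        assert compute_metrics(yte, pred, scores).auc >= 0.95

    def test_single_class_training_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError):
            fit_predict(ClassifierSpec(), X, np.array(["R"] * 5), X)

    def test_knn_matches_sklearn_reference(self):
        """The final KNN estimator is sklearn's; spot-check votes by hand."""
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(6)
        Xtr = rng.standard_normal((30, 4))
        ytr = (rng.uniform(size=30) < 0.4).astype(int)
        if len(set(ytr)) < 2:
            ytr[0] = 1 - ytr[0]
        Xte = rng.standard_normal((10, 4))
        ref = KNeighborsClassifier(n_neighbors=3).fit(Xtr, ytr)
        spec = ClassifierSpec(kind="KNN", knn_k_grid=(3,))
        pred, _ = fit_predict(spec, Xtr, ytr, Xte)
        np.testing.assert_array_equal(pred, ref.predict(Xte))


class TestNestedLooCv:
    def _cohort(self, n1=12, n0=24, f=15, effect=3.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n1 + n0, f))
        y = make_labels(n1, n0)
        X[:n1, 0] += effect
        return X, y

    def test_each_fold_trains_without_heldout_row(self):
        X, y = self._cohort()
        sel = SelectionSpec(mrmr_top=10, sfs_max=3)
        res = nested_loo_cv(X, y, ClassifierSpec(kind="KNN"), sel, seed=1)
        assert res.y_pred.size == X.shape[0]
        assert len(res.selected_features) == X.shape[0]

    def test_separable_cohort_high_auc(self):
        X, y = self._cohort(effect=4.0)
        sel = SelectionSpec(mrmr_top=10, sfs_max=3)
        res = nested_loo_cv(X, y, ClassifierSpec(kind="KNN"), sel, seed=1)
        assert res.metrics.auc >= 0.9

    def test_deterministic_given_seed(self):
        X, y = self._cohort()
        sel = SelectionSpec(mrmr_top=10, sfs_max=3)
        a = nested_loo_cv(X, y, ClassifierSpec(kind="KNN"), sel, seed=5)
        b = nested_loo_cv(X, y, ClassifierSpec(kind="KNN"), sel, seed=5)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.y_pred, b.y_pred)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nested_loo_cv(np.ones((2, 2)), np.array(["R", "NR"]), ClassifierSpec())


class TestHoldoutCv:
    def test_split_sizes_and_error_definitions(self):
        rng = np.random.default_rng(7)
        n1, n0 = 24, 56
        X = rng.standard_normal((n1 + n0, 10))
        X[:n1, 0] += 3.0
        y = make_labels(n1, n0)
        sel = SelectionSpec(mrmr_top=8, sfs_max=3)
        res = holdout_cv(X, y, ClassifierSpec(kind="KNN"), sel, test_fraction=0.2, repeats=4, seed=2)
        # stratified 20%: 5 NR + 11 R per repeat
        assert res.y_true.size == 4 * 16
        assert res.bias_error == pytest.approx(100.0 - res.test_metrics_mean["accuracy"])
        assert res.variance_error >= 0.0

    def test_fraction_leaving_tiny_test_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((30, 4))
        y = make_labels(5, 25)
        with pytest.raises(ValueError):
            holdout_cv(X, y, ClassifierSpec(kind="KNN"), SelectionSpec(mrmr_top=4, sfs_max=2),
                       test_fraction=0.1, repeats=2, seed=0)


class TestMetrics:
    def test_perfect_classifier(self):
        y = np.array([1, 1, 0, 0])
        m = compute_metrics(y, y, scores=np.array([0.9, 0.8, 0.1, 0.2]))
        assert (m.sensitivity, m.specificity, m.accuracy) == (100.0, 100.0, 100.0)
        assert m.auc == 1.0

    def test_reported_confusion_matrix_rates(self):
        """TP=37 FN=10 TN=139 FP=22 on n=208 (47 positive): sens 78.7%,
        spec 86.3%, acc 84.6%, PPV 62.7%, NPV 93.3%."""
        y_true = np.array([1] * 47 + [0] * 161)
        y_pred = np.array([1] * 37 + [0] * 10 + [0] * 139 + [1] * 22)
        m = compute_metrics(y_true, y_pred)
        assert m.sensitivity == pytest.approx(78.7, abs=0.05)
        assert m.specificity == pytest.approx(86.3, abs=0.05)
        assert m.accuracy == pytest.approx(84.6, abs=0.05)
        assert m.ppv == pytest.approx(62.7, abs=0.05)
        assert m.npv == pytest.approx(93.3, abs=0.05)

    def test_ppv_consistent_with_bayes(self):
        """PPV from (sens, spec, prevalence) via Bayes matches the matrix."""
        rng = np.random.default_rng(1)
        y = (rng.uniform(size=300) < 0.25).astype(int)
        pred = np.where(rng.uniform(size=300) < 0.8, y, 1 - y)
        m = compute_metrics(y, pred)
        prev = y.mean()
        se, sp = m.sensitivity / 100, m.specificity / 100
        ppv_bayes = 100 * se * prev / (se * prev + (1 - sp) * (1 - prev))
        assert m.ppv == pytest.approx(ppv_bayes, abs=1e-9)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(2)
        y = (rng.uniform(size=2000) < 0.3).astype(int)
        m = compute_metrics(y, y * 0, scores=rng.uniform(size=2000))
        assert 0.45 < m.auc < 0.55

    def test_zero_denominator_flagged(self):
        m = compute_metrics(np.zeros(4, int), np.zeros(4, int))
        assert np.isnan(m.sensitivity) and m.specificity == 100.0


class TestPooledGroupMean:
    def test_residual_tumour_size(self):
        """Subgroup means 1.8 / 5.9 cm with sizes 161 / 47 pool to 2.7 cm."""
        assert pooled_group_mean([1.8, 5.9], [161, 47], ndigits=1) == 2.7

    def test_luminal_a_percentage(self):
        assert pooled_group_mean([36, 64], [161, 47], ndigits=0) == 42

    def test_equal_means_preserved(self):
        assert pooled_group_mean([5.0, 5.0], [10, 90]) == pytest.approx(5.0)

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            pooled_group_mean([1.0], [0])
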