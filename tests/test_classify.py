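"""PCA model, stratified splitting, grid-searched classifiers, reports."""

import numpy as np
import pytest

import footmotion as fm
from footmotion.classify import (
    evaluate,
    f1_from_precision_recall,
    fit_pca,
    inverse_transform_pca,
    macro_average,
    split_dataset,
    train_classifier,
    transform_pca,
)
from footmotion.recording import ValidationError

from _oracles import svm_dual_oracle


class TestPCA:
    def test_rank_one_data(self, rng):
        t = rng.normal(size=40)
        X = np.outer(t, [1.0, -2.0, 0.5]) + [3.0, 1.0, -1.0]
        model = fit_pca(X, variance_kept=0.9)
        assert model.n_components == 1
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-9)

    def test_full_retention_reconstructs(self, rng):
        X = rng.normal(size=(30, 5))
        model = fit_pca(X, variance_kept=1.0)
        Z = transform_pca(model, X)
        back = inverse_transform_pca(model, Z)
        standardized = (X - model.mean_) / model.scale_
        np.testing.assert_allclose(back, standardized, atol=1e-9)

    def test_component_variances_non_increasing(self, rng):
        X = rng.normal(size=(50, 34))
        model = fit_pca(X, variance_kept=1.0)
        ratios = model.explained_variance_ratio_
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() == pytest.approx(1.0, abs=1e-9)
        # scores are uncorrelated: covariance is diagonal
        Z = transform_pca(model, X)
        cov = np.cov(Z, rowvar=False, bias=True)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-9)

    def test_training_mean_maps_to_origin(self, rng):
        X = rng.normal(size=(25, 6))
        model = fit_pca(X)
        score = transform_pca(model, X.mean(axis=0))
        np.testing.assert_allclose(score, 0.0, atol=1e-9)

    def test_scores_match_projection_oracle(self, rng):
        """Each score is the dot product of the standardized row with the
        loading, computed by an explicit loop."""
        X = rng.normal(size=(20, 7))
        model = fit_pca(X, variance_kept=1.0)
        Z = transform_pca(model, X)
        standardized = (X - model.mean_) / model.scale_
        for i in range(X.shape[0]):
            for j in range(model.n_components):
                expected = sum(
                    standardized[i, k] * model.components_[j, k]
                    for k in range(X.shape[1])
                )
                assert Z[i, j] == pytest.approx(expected, abs=1e-9)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(40, 10))
        model = fit_pca(X, variance_kept=1.0)
        G = model.components_ @ model.components_.T
        np.testing.assert_allclose(G, np.eye(model.n_components), atol=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            fit_pca(np.zeros((1, 4)))


class TestSplitDataset:
    def test_study_sized_split(self):
        """264 + 250 samples at 0.8 give 411 training and 103 test rows."""
        y = np.array(["passing"] * 264 + ["shooting"] * 250)
        X = np.zeros((514, 3))
        train, test = split_dataset(X, y, 0.8, seed=0)
        assert len(train) == 411 and len(test) == 103
        assert (y[train] == "passing").sum() == 211
        assert (y[train] == "shooting").sum() == 200

    def test_deterministic_per_seed(self):
        y = np.array([0, 1] * 30)
        X = np.zeros((60, 2))
        t1, s1 = split_dataset(X, y, 0.8, seed=5)
        t2, s2 = split_dataset(X, y, 0.8, seed=5)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(s1, s2)
        t3, _ = split_dataset(X, y, 0.8, seed=6)
        assert not np.array_equal(t1, t3)

    def test_partition_property(self):
        y = np.array([0] * 25 + [1] * 35)
        X = np.zeros((60, 2))
        train, test = split_dataset(X, y, 0.8, seed=1)
        assert sorted(np.concatenate([train, test]).tolist()) == list(range(60))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            split_dataset(np.zeros((10, 2)), np.zeros(10), 0.8, 0)


class TestTrainClassifier:
    def separable_clouds(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([
            rng.normal([-3, 0], 0.3, (n // 2, 2)),
            rng.normal([3, 0], 0.3, (n // 2, 2)),
        ])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_separable_clouds_select_linear_c1(self):
        X, y = self.separable_clouds()
        model = train_classifier(X, y, "svm", seed=0)
        assert model.params["C"] == 1.0
        assert model.params["kernel"] == "linear"
        assert model.cv_accuracy == 1.0
        Xt, yt = self.separable_clouds(seed=99)
        assert np.mean(model.predict(Xt) == yt) == 1.0

    def test_tie_break_prefers_smallest_gamma(self):
        X, y = self.separable_clouds()
        model = train_classifier(X, y, "svm", seed=0)
        # linear kernel ignores gamma, so all gamma values tie; the smallest wins
        assert model.params["gamma"] == 1e-5

    def test_grid_search_invariant_to_row_shuffle(self, rng):
        X, y = self.separable_clouds(seed=3)
        m1 = train_classifier(X, y, "svm", seed=4)
        perm = rng.permutation(len(y))
        m2 = train_classifier(X[perm], y[perm], "svm", seed=4)
        assert m1.params == m2.params

    def test_baseline_parameters(self):
        X, y = self.separable_clouds()
        knn = train_classifier(X, y, "knn", seed=0)
        assert knn.params == {"n_neighbors": 4}
        tree = train_classifier(X, y, "tree", seed=0)
        assert tree.params == {"min_samples_split": 3, "max_depth": 6}

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            train_classifier(np.zeros((10, 2)), np.zeros(10), "svm")

    def test_unknown_algorithm_rejected(self):
        X, y = self.separable_clouds()
        with pytest.raises(ValidationError):
            train_classifier(X, y, "forest")

    def test_decision_function_matches_dual_qp_oracle(self):
        """Production linear SVM equals the brute-force KKT solution on a
        handful of tiny instances."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 5:
            n = int(rng.integers(4, 9))
            y_pm = np.concatenate([np.ones(n // 2), -np.ones(n - n // 2)])
            X = rng.normal(0, 1, (n, 2)) + np.outer(y_pm, rng.uniform(0.5, 1.5, 2))
            try:
                alpha, b, w = svm_dual_oracle(X, y_pm, C=1.0)
            except RuntimeError:
                continue
            grid = {"C": [1.0], "gamma": [1e-4], "kernel": ["linear"]}
            model = train_classifier(X, (y_pm > 0).astype(int), "svm", grid,
                                     folds=2, seed=0)
            probes = np.vstack([X, rng.normal(0, 2, (5, 2))])
            np.testing.assert_allclose(
                model.decision_function(probes), probes @ w + b, atol=1e-6
            )
            checked += 1


class TestEvaluate:
    def test_perfect_predictions(self):
        X, y = np.zeros((10, 2)), np.array([0] * 5 + [1] * 5)
        model = fm.ClassifierModel("svm", {}, None, 1.0)
        model.predict = lambda X_: y
        report = evaluate(model, X, y)
        assert report.overall_accuracy == 1.0
        for lab in report.labels:
            assert report.per_class[lab]["f1"] == 1.0
        off_diag = np.array(report.confusion)[~np.eye(2, dtype=bool)]
        assert np.all(off_diag == 0)

    def test_metrics_from_constructed_confusion(self):
        """Hand computation on a chosen 2x2 table: 40 passing (36 right),
        40 shooting (34 right)."""
        y = np.array(["passing"] * 40 + ["shooting"] * 40)
        pred = np.array(
            ["passing"] * 36 + ["shooting"] * 4 + ["passing"] * 6 + ["shooting"] * 34
        )
        model = fm.ClassifierModel("svm", {}, None, 0.0)
        model.predict = lambda X_: pred
        report = evaluate(model, np.zeros((80, 1)), y)
        assert report.confusion == [[36, 4], [6, 34]]
        assert report.per_class["passing"]["precision"] == pytest.approx(36 / 42)
        assert report.per_class["passing"]["recall"] == pytest.approx(36 / 40)
        p, r = 36 / 42, 36 / 40
        assert report.per_class["passing"]["f1"] == pytest.approx(2 * p * r / (p + r))
        assert report.overall_accuracy == pytest.approx(70 / 80)

    def test_precision_alias_accuracy(self):
        y = np.array([0] * 6 + [1] * 6)
        model = fm.ClassifierModel("svm", {}, None, 0.0)
        model.predict = lambda X_: np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 0, 1])
        report = evaluate(model, np.zeros((12, 1)), y)
        for lab in report.labels:
            assert report.per_class[lab]["accuracy"] == report.per_class[lab]["precision"]

    def test_macro_is_unweighted_mean(self):
        assert macro_average([0.8, 0.6]) == pytest.approx(0.7)

    def test_f1_formula(self):
        assert f1_from_precision_recall(0.5, 1.0) == pytest.approx(2 / 3)
        assert f1_from_precision_recall(0.0, 0.0) == 0.0

    def test_single_class_test_set_rejected(self):
        model = fm.ClassifierModel("svm", {}, None, 0.0)
        model.predict = lambda X_: np.zeros(4)
        with pytest.raises(ValidationError):
            evaluate(model, np.zeros((4, 1)), np.zeros(4))
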