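"""NCA feature weighting, SVM cross-validation, and the metric panel."""

import numpy as np
import pytest

from vagdfa import classify


class TestNcaWeights:
    def test_informative_feature_dominates(self):
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(10):
            y = rng.permutation(np.repeat([0, 1], 30))
            X = rng.standard_normal((60, 12))
            X[:, 0] = y
            res = classify.nca_weights(X, y, seed=int(rng.integers(2**31)))
            wins += res.weights[0] > 0.5
        assert wins >= 9

    def test_pure_noise_weights_stay_flat(self):
        rng = np.random.default_rng(1)
        below = 0
        n_runs = 20
        for _ in range(n_runs):
            y = rng.permutation(np.repeat([0, 1], 30))
            X = rng.standard_normal((60, 12))
            res = classify.nca_weights(X, y, seed=int(rng.integers(2**31)))
            below += res.weights.max() < 0.3
        assert below >= 0.8 * n_runs

    def test_duplicated_informative_feature_outranks_noise(self):
        rng = np.random.default_rng(2)
        y = rng.permutation(np.repeat([0, 1], 30))
        X = rng.standard_normal((60, 8))
        X[:, 0] = y + 0.1 * rng.standard_normal(60)
        X[:, 1] = X[:, 0]
        res = classify.nca_weights(X, y, seed=3)
        combined = res.weights[0] + res.weights[1]
        assert combined > res.weights[2:].max()

    def test_weights_normalized(self, rng):
        y = rng.integers(0, 2, 40)
        res = classify.nca_weights(rng.standard_normal((40, 5)), y, seed=0)
        assert abs(res.weights.sum() - 1.0) < 1e-9

    def test_non_finite_features_rejected(self):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            classify.nca_weights(X, np.repeat([0, 1], 5), seed=0)


class TestSelectByWeight:
    def test_threshold_selection(self):
        res = classify.NcaResult(
            weights=np.array([0.5, 0.3, 0.1, 0.04, 0.03, 0.03]),
            raw_weights=np.ones(6), kept=(), lam=0.1, iterations=1, objective=0.0,
        )
        assert classify.select_by_weight(res) == (0, 1, 2)

    def test_uniform_twelve_features_all_kept(self):
        res = classify.NcaResult(
            weights=np.full(12, 1 / 12), raw_weights=np.ones(12),
            kept=(), lam=0.1, iterations=1, objective=0.0,
        )
        assert classify.select_by_weight(res) == tuple(range(12))

    def test_empty_selection_falls_back_to_top3(self):
        res = classify.NcaResult(
            weights=np.array([0.3, 0.25, 0.2, 0.15, 0.1]),
            raw_weights=np.ones(5), kept=(), lam=0.1, iterations=1, objective=0.0,
        )
        with pytest.warns(UserWarning):
            out = classify.select_by_weight(res, threshold=0.9)
        assert out == (0, 1, 2)


class TestMetrics:
    def test_hand_arithmetic(self):
        m = classify.metrics_from_confusion(tp=9, fn=1, tn=8, fp=2)
        assert m["sensitivity"] == 0.9
        assert m["specificity"] == 0.8
        assert np.isclose(m["precision"], 9 / 11)
        assert np.isclose(m["f1"], 2 * (9 / 11) * 0.9 / (9 / 11 + 0.9))
        assert m["recall"] == m["sensitivity"]

    def test_perfect_classifier(self):
        m = classify.metrics_from_confusion(tp=10, fn=0, tn=10, fp=0)
        assert all(m[k] == 1.0 for k in ("accuracy", "sensitivity", "specificity", "f1"))

    def test_zero_denominator_flagged(self):
        m = classify.metrics_from_confusion(tp=0, fn=5, tn=5, fp=0)
        assert np.isnan(m["precision"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify.metrics_from_confusion(-1, 0, 0, 1)


class TestRocAuc:
    def test_scores_equal_labels_perfect(self):
        labels = np.array([0, 1, 0, 1, 1])
        auc, _ = classify.roc_auc(labels.astype(float), labels)
        assert auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(20):
            labels = np.r_[np.zeros(100), np.ones(100)].astype(int)
            auc, _ = classify.roc_auc(rng.standard_normal(200), labels)
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=50), 1)
            auc, _ = classify.roc_auc(scores, labels)
            assert abs(auc - roc_auc_score(labels, scores)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classify.roc_auc(np.arange(5.0), np.ones(5, dtype=int))


class TestSvmCv:
    def _blobs(self, rng, n=60, d=5, sep=4.0):
        X = np.vstack([rng.standard_normal((n, d)), rng.standard_normal((n, d)) + sep / np.sqrt(d)])
        y = np.array(["HC"] * n + ["OA"] * n)
        return X, y

    def test_separable_blobs_high_accuracy(self, rng):
        X, y = self._blobs(rng)
        report = classify.svm_rbf_cv(X, y, k=5, seed=0)
        assert report.mean["accuracy"] >= 0.95
        assert report.mean["auc"] >= 0.95

    def test_permuted_labels_chance_level(self, rng):
        X, y = self._blobs(rng)
        accs = []
        for s in range(10):
            yp = np.random.default_rng(s).permutation(y)
            accs.append(classify.svm_rbf_cv(X, yp, k=5, seed=0).mean["accuracy"])
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_deterministic_under_seed(self, rng):
        X, y = self._blobs(rng, n=20)
        r1 = classify.svm_rbf_cv(X, y, k=5, seed=3)
        r2 = classify.svm_rbf_cv(X, y, k=5, seed=3)
        assert r1.folds.equals(r2.folds)

    def test_metric_identities_per_fold(self, rng):
        X, y = self._blobs(rng, n=25, sep=1.5)
        report = classify.svm_rbf_cv(X, y, k=5, seed=1)
        for _, row in report.folds.iterrows():
            assert row["recall"] == row["sensitivity"]
            if np.isfinite(row["f1"]):
                expected = 2 * row["precision"] * row["recall"] / (row["precision"] + row["recall"])
                assert np.isclose(row["f1"], expected)
        for (tp, fn, tn, fp) in report.confusions:
            assert tp + fn + tn + fp == len(y) // 5

    def test_class_smaller_than_k_rejected(self, rng):
        X = rng.standard_normal((8, 3))
        y = np.array(["HC"] * 3 + ["OA"] * 5)
        with pytest.raises(ValueError):
            classify.svm_rbf_cv(X, y, k=5, seed=0)
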