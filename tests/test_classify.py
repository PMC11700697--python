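"""Classification: fold plans, KNN, PLSDA, Q/T2 screening, SVMDA, reports."""

import numpy as np
import pytest

from pasa.classify import (
    ConfusionMatrix,
    FoldPlan,
    KNNClassifier,
    confusion_from_predictions,
    evaluate,
    gaussian_threshold,
    knn_classify,
    make_classifier,
    plsda_fit,
    plsda_predict,
    qt2_outlier_filter,
    roc_auc,
    stratified_kfold,
    svmda_train,
)


class TestFoldPlan:
    def test_balanced_5_plus_5_test_folds(self):
        y = np.array([0] * 50 + [1] * 50)
        plan = stratified_kfold(y, k=10, seed=3)
        assert len(plan) == 10
        for _, test in plan:
            assert len(test) == 10
            assert np.sum(y[test] == 0) == 5 and np.sum(y[test] == 1) == 5

    def test_same_seed_same_plan(self):
        y = np.array([0] * 20 + [1] * 20)
        p1 = stratified_kfold(y, k=5, seed=7)
        p2 = stratified_kfold(y, k=5, seed=7)
        assert all(
            np.array_equal(a[1], b[1]) for a, b in zip(p1.folds, p2.folds)
        )

    def test_test_folds_partition_all_samples(self):
        y = np.array([0] * 50 + [1] * 50)
        plan = stratified_kfold(y, k=10, seed=1)
        union = np.sort(np.concatenate([test for _, test in plan]))
        assert np.array_equal(union, np.arange(100))

    def test_k_larger_than_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([0, 0, 1, 1]), k=3)


class TestKNN:
    def test_duplicate_of_tight_cluster_gets_its_class(self, rng):
        cluster0 = rng.normal(0.0, 0.01, size=(10, 2))
        cluster1 = rng.normal(5.0, 0.01, size=(10, 2))
        X = np.vstack([cluster0, cluster1])
        y = np.array([0] * 10 + [1] * 10)
        pred, _ = knn_classify(X, y, cluster1[:1], k=3)
        assert pred[0] == 1

    def test_separated_clusters_perfect_accuracy(self, rng):
        X_train = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(10, 1, (25, 3))])
        y_train = np.array([0] * 25 + [1] * 25)
        X_test = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(10, 1, (10, 3))])
        pred, votes = knn_classify(X_train, y_train, X_test, k=5)
        assert np.array_equal(pred, np.array([0] * 10 + [1] * 10))
        assert np.all((votes >= 0) & (votes <= 1))

    def test_matches_brute_force_sort_oracle(self, rng):
        X_train = rng.normal(size=(30, 4))
        y_train = (rng.random(30) > 0.5).astype(int)
        X_test = rng.normal(size=(12, 4))
        pred, _ = knn_classify(X_train, y_train, X_test, k=3)
        for i, x in enumerate(X_test):
            dists = [(np.sum((x - t) ** 2), j) for j, t in enumerate(X_train)]
            nearest = [j for _, j in sorted(dists)[:3]]
            expect = int(np.sum(y_train[nearest] == 1) > 1.5)
            assert pred[i] == expect

    @pytest.mark.parametrize("k", [2, 4, 11])
    def test_invalid_k_rejected(self, k, rng):
        with pytest.raises(ValueError):
            knn_classify(rng.normal(size=(20, 2)), np.zeros(20, int), rng.normal(size=(1, 2)), k=k)


class TestPLSDA:
    def test_symmetric_gaussians_threshold_midpoint(self, rng):
        s0 = 0.2 + 0.05 * rng.standard_normal(500)
        s1 = 0.6 + s0  # identical shape shifted: equal variance -> midpoint
        assert gaussian_threshold(s0, s1) == pytest.approx(
            (s0.mean() + s1.mean()) / 2.0, abs=1e-9
        )

    def test_unequal_variance_threshold_is_likelihood_crossing(self):
        rng = np.random.default_rng(8)
        s0 = 0.2 + 0.05 * rng.standard_normal(4000)
        s1 = 0.8 + 0.15 * rng.standard_normal(4000)
        thr = gaussian_threshold(s0, s1)
        from scipy.stats import norm

        d0 = norm.pdf(thr, s0.mean(), s0.std(ddof=1))
        d1 = norm.pdf(thr, s1.mean(), s1.std(ddof=1))
        assert d0 == pytest.approx(d1, rel=1e-6)
        assert s0.mean() < thr < s1.mean()

    def test_separated_classes_high_accuracy(self, rng):
        direction = rng.normal(size=6)
        y = np.array([0] * 40 + [1] * 40)
        X = rng.normal(size=(80, 6)) + 4.0 * y[:, None] * direction
        model = plsda_fit(X[::2], y[::2])
        pred, _ = plsda_predict(model, X[1::2])
        assert np.mean(pred == y[1::2]) >= 0.95
        assert 1 <= model.n_lv <= 3

    def test_matches_independent_pls1_oracle(self, rng):
        """sklearn NIPALS path vs a hand-written SVD/deflation PLS1."""
        X = rng.normal(size=(30, 5))
        y = (rng.random(30) > 0.5).astype(float)
        model = plsda_fit(X, y, max_lv=2)
        _, scores = plsda_predict(model, X)
        oracle = _pls1_oracle_predict(X, y, model.n_lv, X)
        assert np.abs(scores - oracle).max() < 1e-8


def _pls1_oracle_predict(X, y, n_components, X_new):
    """Independent PLS1: weights from X'y, sequential deflation, in the
    same centered/scaled coordinates used by the fitted model."""
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    y_mean, y_sd = y.mean(), y.std(ddof=1)
    E = (X - x_mean) / x_sd
    f = (y - y_mean) / y_sd
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t = E @ w
        p = E.T @ t / (t @ t)
        q = f @ t / (t @ t)
        E = E - np.outer(t, p)
        f = f - q * t
        W.append(w), P.append(p), Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    beta = W @ np.linalg.inv(P.T @ W) @ Q
    return y_mean + y_sd * (((X_new - x_mean) / x_sd) @ beta)


class TestQT2Filter:
    def test_clean_data_keeps_almost_everything(self, rng):
        X = rng.multivariate_normal(np.zeros(5), np.eye(5), size=90)
        y = np.tile([0.0, 1.0], 45)
        keep = qt2_outlier_filter(X, y)
        assert len(keep) >= 87

    def test_gross_outlier_removed_first_iteration(self, rng):
        """A sample displaced far along the model direction (T2) and across
        the residual space (Q) is excluded in the first pass."""
        y = np.tile([0.0, 1.0], 30)
        X = rng.normal(size=(60, 8))
        X[:, 0] += 3.0 * y  # the retained latent direction
        X[7, 0] += 8.0
        X[7, 1:] += 6.0 * (-1.0) ** np.arange(7)
        keep = qt2_outlier_filter(X, y, max_iter=1, max_lv=2)
        assert 7 not in keep
        assert len(keep) == 59

    def test_no_outliers_returns_unchanged(self, rng):
        X = np.column_stack([np.linspace(0, 1, 20), np.linspace(1, 0, 20)])
        X = X + 0.01 * rng.normal(size=X.shape)
        y = np.tile([0.0, 1.0], 10)
        keep = qt2_outlier_filter(X, y)
        assert np.array_equal(np.sort(keep), np.arange(20))


class TestSVMDA:
    def test_separable_data_perfect_training_point_exists(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (20, 2)), rng.normal(6, 0.5, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model, c, gamma = svmda_train(X, y, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_xor_needs_the_nonlinear_kernel(self, rng):
        """RBF separates the XOR pattern; a linear rule cannot."""
        centers = np.array([[0, 0], [4, 4], [0, 4], [4, 0]], float)
        labels = np.array([0, 0, 1, 1])
        X = np.vstack([c + rng.normal(0, 0.4, (30, 2)) for c in centers])
        y = np.repeat(labels, 30)
        order = rng.permutation(len(y))
        X, y = X[order], y[order]
        model, _, _ = svmda_train(X[:80], y[:80], seed=1)
        rbf_acc = np.mean(model.predict(X[80:]) == y[80:])
        from sklearn.linear_model import LogisticRegression

        linear = LogisticRegression().fit(X[:80], y[:80])
        linear_acc = np.mean(linear.predict(X[80:]) == y[80:])
        assert rbf_acc >= 0.9
        assert linear_acc <= 0.6

    def test_tie_break_prefers_smaller_c_then_gamma(self, rng):
        """On trivially separable data many grid points are perfect; the
        reported pair must be the lexicographically smallest (c, gamma)."""
        X = np.vstack([rng.normal(0, 0.1, (15, 1)), rng.normal(10, 0.1, (15, 1))])
        y = np.array([0] * 15 + [1] * 15)
        exponents = np.array([0.0, 1.0, 2.0])
        _, c, gamma = svmda_train(X, y, grid_exponents=exponents, seed=0)
        perfect = []
        from pasa.classify import stratified_kfold as skf
        inner = [(tr, te) for tr, te in skf(y, k=5, seed=0)]
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC
        for ce in 10.0 ** exponents:
            for ge in 10.0 ** exponents:
                errs = 0
                for tr, te in inner:
                    sc = StandardScaler().fit(X[tr])
                    m = SVC(C=ce, gamma=ge, max_iter=3000).fit(sc.transform(X[tr]), y[tr])
                    errs += np.sum(m.predict(sc.transform(X[te])) != y[te])
                if errs == 0:
                    perfect.append((ce, ge))
        assert (c, gamma) == min(perfect)


class TestReports:
    def test_printed_confusion_metric_triple(self):
        """TP 33 / FN 17 / TN 39 / FP 11 gives 66 / 78 / 72 percent."""
        cm = ConfusionMatrix(tp=33, fn=17, tn=39, fp=11)
        assert cm.sensitivity_pct == pytest.approx(66.0)
        assert cm.specificity_pct == pytest.approx(78.0)
        assert cm.accuracy_pct == pytest.approx(72.0)

    def test_accuracy_identity(self):
        cm = ConfusionMatrix(tp=33, fn=17, tn=39, fp=11)
        p, n = cm.tp + cm.fn, cm.tn + cm.fp
        assert cm.accuracy_pct == pytest.approx(
            (cm.sensitivity_pct * p + cm.specificity_pct * n) / (p + n)
        )

    def test_perfect_scores_auc_one(self):
        y = np.array([0] * 5 + [1] * 5)
        scores = np.array([0.1, 0.2, 0.15, 0.3, 0.25, 0.8, 0.9, 0.7, 0.95, 0.85])
        _, _, auc = roc_auc(y, scores)
        assert auc == pytest.approx(1.0)

    def test_random_scores_auc_half(self, rng):
        y = (rng.random(1000) > 0.5).astype(int)
        _, _, auc = roc_auc(y, rng.random(1000))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_label_swap_swaps_sensitivity_specificity(self, rng):
        y = (rng.random(60) > 0.5).astype(int)
        pred = (rng.random(60) > 0.4).astype(int)
        cm = confusion_from_predictions(y, pred)
        cm_swapped = confusion_from_predictions(1 - y, 1 - pred)
        assert cm.sensitivity_pct == pytest.approx(cm_swapped.specificity_pct)
        assert cm.specificity_pct == pytest.approx(cm_swapped.sensitivity_pct)

    def test_evaluate_pooled_identity_and_coverage(self, rng):
        direction = rng.normal(size=4)
        y = np.array([0] * 20 + [1] * 20)
        X = rng.normal(size=(40, 4)) + 2.0 * y[:, None] * direction
        plan = stratified_kfold(y, k=5, seed=2)
        report = evaluate(X, y, KNNClassifier(k=3), plan)
        cm = report.pooled_confusion
        assert cm.total == 40
        p, n = cm.tp + cm.fn, cm.tn + cm.fp
        assert cm.accuracy_pct == pytest.approx(
            (cm.sensitivity_pct * p + cm.specificity_pct * n) / (p + n)
        )
        assert 0.0 <= report.auc <= 1.0

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("forest")
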