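"""Supervised normal-vs-cancer discrimination on APSD spectra.

Three classifiers suited to small spectroscopic datasets — KNN (Euclidean
majority vote), PLSDA (PLS1 regression of the 0/1 response with a
class-conditional Gaussian decision threshold and Q/T2 outlier screening),
and SVMDA (RBF-kernel SVM with a log-uniform c/gamma grid search) — are
validated by seeded stratified 10-fold cross-validation. Reports carry
per-fold calibration and testing accuracy/sensitivity/specificity, the
pooled confusion matrix (cancer = positive), and a pooled-score ROC/AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


# ---------------------------------------------------------------------------
# fold planning


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint, class-stratified calibration/testing index splits."""

    folds: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        test_union = np.concatenate([test for _, test in self.folds])
        if len(np.unique(test_union)) != len(test_union):
            raise ValueError("test folds must be disjoint")

    def __iter__(self):
        return iter(self.folds)

    def __len__(self) -> int:
        return len(self.folds)


def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded stratified k-fold plan (each test fold preserves class balance)."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError("fold count exceeds the smallest class size")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return FoldPlan([(train, test) for train, test in splitter.split(np.zeros(len(y)), y)])


# ---------------------------------------------------------------------------
# KNN


def knn_classify(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    k: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean K-nearest-neighbor vote: (predictions, cancer-vote fraction).

    K must be odd with 3 <= K <= 9 (vote ties impossible for two classes);
    distance ties are broken deterministically toward the lower sample index.
    """
    if k % 2 == 0 or not 3 <= k <= 9:
        raise ValueError("K must be odd with 3 <= K <= 9")
    if k > len(X_train):
        raise ValueError("K cannot exceed the training-set size")
    X_train = np.asarray(X_train, float)
    X_test = np.atleast_2d(np.asarray(X_test, float))
    y_train = np.asarray(y_train)
    d2 = ((X_test[:, None, :] - X_train[None, :, :]) ** 2).sum(axis=2)
    neighbors = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = (y_train[neighbors] == 1).mean(axis=1)
    return (votes > 0.5).astype(int), votes


class KNNClassifier:
    """Fit/predict wrapper so KNN plugs into the shared evaluation loop."""

    def __init__(self, k: int = 3):
        self.k = k
        self.name = "knn"
        self.params: dict = {"K": k}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        self._X, self._y = np.asarray(X, float), np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return knn_classify(self._X, self._y, X, self.k)


# ---------------------------------------------------------------------------
# PLSDA


def _kaiser_n_components(X: np.ndarray, cap: int) -> int:
    """Number of latent variables: components of the column-standardized
    predictor matrix with eigenvalue (explained variance) > 1, at least 1."""
    sd = X.std(axis=0, ddof=1)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    ev = PCA(n_components=min(Xs.shape)).fit(Xs).explained_variance_
    n = int(np.sum(ev > 1.0))
    return max(1, min(n, cap, min(X.shape) - 1, X.shape[1]))


def gaussian_threshold(
    scores0: np.ndarray, scores1: np.ndarray
) -> float:
    """Equal-likelihood crossing of class-conditional Gaussians.

    Fits N(mu0, s0^2) to normal-class scores and N(mu1, s1^2) to
    cancer-class scores and returns the likelihood crossing between the two
    means; with (near-)equal variances this reduces to the midpoint.
    """
    mu0, s0 = float(np.mean(scores0)), float(np.std(scores0, ddof=1))
    mu1, s1 = float(np.mean(scores1)), float(np.std(scores1, ddof=1))
    if not np.isfinite(s0) or not np.isfinite(s1) or min(s0, s1) <= 0:
        return (mu0 + mu1) / 2.0
    if abs(s0 - s1) < 1e-6 * max(s0, s1):
        # near-equal variances: the quadratic is ill-conditioned and the
        # crossing degenerates to the midpoint anyway
        return (mu0 + mu1) / 2.0
    # quadratic from equating Gaussian log-densities
    a = 1.0 / s1**2 - 1.0 / s0**2
    b = 2.0 * (mu0 / s0**2 - mu1 / s1**2)
    c = mu1**2 / s1**2 - mu0**2 / s0**2 - 2.0 * np.log(s0 / s1)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    if roots.size == 0:
        return (mu0 + mu1) / 2.0
    lo, hi = min(mu0, mu1), max(mu0, mu1)
    inside = roots[(roots >= lo) & (roots <= hi)]
    if inside.size:
        return float(inside[0])
    return float(roots[np.argmin(np.abs(roots - (mu0 + mu1) / 2.0))])


@dataclass
class PLSDAModel:
    pls: PLSRegression
    n_lv: int
    threshold: float


def plsda_fit(X: np.ndarray, y: np.ndarray, max_lv: int = 10) -> PLSDAModel:
    """PLS1 regression of the 0/1 response with a Gaussian decision threshold."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("PLSDA needs >= 2 samples per class")
    n_lv = _kaiser_n_components(X, max_lv)
    pls = PLSRegression(n_components=n_lv, scale=True)
    pls.fit(X, y)
    scores = pls.predict(X).ravel()
    threshold = gaussian_threshold(scores[y == 0], scores[y == 1])
    return PLSDAModel(pls, n_lv, threshold)


def plsda_predict(model: PLSDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = model.pls.predict(np.asarray(X, float)).ravel()
    return (scores > model.threshold).astype(int), scores


def qt2_outlier_filter(
    X: np.ndarray,
    y: np.ndarray,
    confidence: float = 0.99,
    max_lv: int = 10,
    max_iter: int = 10,
    mode: str = "both",
) -> np.ndarray:
    """Iterative Q-residual / Hotelling-T2 outlier screening.

    Fits a PLS1 decomposition, computes each training sample's Hotelling T2
    (on the X-scores, F-distribution limit) and Q residual (squared
    off-model X residual, Jackson-Mudholkar limit), and removes samples
    exceeding the limits — both by default (``mode="both"``), either with
    ``mode="either"`` — then refits until no sample exceeds, an iteration
    cap is hit, or a further removal would leave < 3 samples in a class.
    Returns the indices of retained samples.
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    keep = np.arange(len(y))
    for _ in range(max_iter):
        Xk, yk = X[keep], y[keep]
        n = len(keep)
        n_lv = _kaiser_n_components(Xk, max_lv)
        pls = PLSRegression(n_components=n_lv, scale=True)
        pls.fit(Xk, yk)
        t = pls.x_scores_
        t_var = t.var(axis=0, ddof=1)
        t2 = np.sum(t**2 / t_var, axis=1)
        t2_limit = (
            n_lv * (n - 1) / (n - n_lv) * stats.f.ppf(confidence, n_lv, n - n_lv)
            if n > n_lv
            else np.inf
        )
        sd = Xk.std(axis=0, ddof=1)
        Xs = (Xk - Xk.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        residual = Xs - t @ pls.x_loadings_.T
        q = np.sum(residual**2, axis=1)
        q_limit = _jackson_mudholkar_limit(Xs, t, pls.x_loadings_, confidence)
        if mode == "both":
            flags = (t2 > t2_limit) & (q > q_limit)
        else:
            flags = (t2 > t2_limit) | (q > q_limit)
        if not flags.any():
            break
        # drop the worst offender first; re-fit before judging the rest
        order = np.argsort(-(t2 / max(t2_limit, 1e-300) + q / max(q_limit, 1e-300)))
        worst = next(i for i in order if flags[i])
        proposal = np.delete(keep, worst)
        y_prop = y[proposal]
        if min((y_prop == 0).sum(), (y_prop == 1).sum()) < 3:
            break
        keep = proposal
    return keep


def _jackson_mudholkar_limit(
    Xs: np.ndarray, scores: np.ndarray, loadings: np.ndarray, confidence: float
) -> float:
    """Q-statistic control limit from the residual covariance eigenvalues."""
    n, p = Xs.shape
    cov_ev = np.linalg.eigvalsh(np.cov(Xs, rowvar=False))[::-1]
    k = scores.shape[1]
    resid_ev = np.clip(cov_ev[k:], 0.0, None)
    th1, th2, th3 = (np.sum(resid_ev**i) for i in (1, 2, 3))
    if th1 <= 0 or th2 <= 0:
        return np.inf
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    if h0 <= 0:
        h0 = 1e-4
    z = stats.norm.ppf(confidence)
    term = (
        z * np.sqrt(2.0 * th2 * h0**2) / th1
        + 1.0
        + th2 * h0 * (h0 - 1.0) / th1**2
    )
    return float(th1 * max(term, 0.0) ** (1.0 / h0))


class PLSDAClassifier:
    """PLSDA pipeline: optional Q/T2 training-set screening, then PLS1 fit."""

    def __init__(self, max_lv: int = 10, outlier_filter: bool = True,
                 confidence: float = 0.99, outlier_mode: str = "both"):
        self.max_lv = max_lv
        self.outlier_filter = outlier_filter
        self.confidence = confidence
        self.outlier_mode = outlier_mode
        self.name = "plsda"
        self.params: dict = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSDAClassifier":
        X, y = np.asarray(X, float), np.asarray(y, float)
        if self.outlier_filter:
            keep = qt2_outlier_filter(
                X, y, self.confidence, self.max_lv, mode=self.outlier_mode
            )
            X, y = X[keep], y[keep]
        self.model = plsda_fit(X, y, self.max_lv)
        self.params = {"LVs": self.model.n_lv}
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return plsda_predict(self.model, X)


# ---------------------------------------------------------------------------
# SVMDA


def svmda_train(
    X: np.ndarray,
    y: np.ndarray,
    grid_exponents: np.ndarray | None = None,
    inner_folds: int = 5,
    seed: int = 0,
) -> tuple[SVC, float, float]:
    """RBF-SVM with a log-uniform grid search over cost c and kernel gamma.

    Predictors are autoscaled (training-set mean/SD) before the RBF kernel,
    the usual preprocessing for spectroscopic discriminant analysis. The
    grid spans 10^-6 to 10^9 (default 16 log-uniform points per axis). Each
    (c, gamma) pair is scored by misclassification fraction under inner
    stratified cross-validation on the calibration data; ties prefer the
    smaller c, then the smaller gamma. The winning pair is refitted on the
    full calibration set. Returns (model, c, gamma); the model is a
    standardize-then-SVC pipeline.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("SVMDA needs both classes in the training data")
    exponents = (
        np.linspace(-6.0, 9.0, 16) if grid_exponents is None else grid_exponents
    )
    values = 10.0**exponents
    inner = stratified_kfold(y, k=min(inner_folds, np.bincount(y.astype(int)).min()), seed=seed)
    # pre-scale each inner split once; the (c, gamma) loop reuses the arrays
    splits = []
    for tr, te in inner:
        scaler = StandardScaler().fit(X[tr])
        splits.append((scaler.transform(X[tr]), y[tr], scaler.transform(X[te]), y[te]))
    n_total = sum(len(yte) for _, _, _, yte in splits)
    best = (np.inf, None, None)
    with warnings.catch_warnings():
        # iteration-capped fits in degenerate grid corners are expected
        warnings.simplefilter("ignore", ConvergenceWarning)
        for c in values:
            for gamma in values:
                errors = 0
                for Xtr, ytr, Xte, yte in splits:
                    model = SVC(C=c, kernel="rbf", gamma=gamma, max_iter=3000)
                    model.fit(Xtr, ytr)
                    errors += int(np.sum(model.predict(Xte) != yte))
                frac = errors / n_total
                if frac < best[0]:  # strict: earlier (smaller c, gamma) wins ties
                    best = (frac, c, gamma)
    _, c, gamma = best
    final = _scaled_svc(c, gamma)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        final.fit(X, y)
    return final, float(c), float(gamma)


def _scaled_svc(c: float, gamma: float) -> Pipeline:
    # max_iter bounds run time in degenerate grid corners (e.g. enormous c
    # with a near-constant kernel); well-posed pairs converge far earlier
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(C=c, kernel="rbf", gamma=gamma, max_iter=3000)),
        ]
    )


class SVMDAClassifier:
    def __init__(self, grid_exponents: np.ndarray | None = None,
                 inner_folds: int = 5, seed: int = 0):
        self.grid_exponents = grid_exponents
        self.inner_folds = inner_folds
        self.seed = seed
        self.name = "svmda"
        self.params: dict = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMDAClassifier":
        y = np.asarray(y).astype(int)
        self.model, c, gamma = svmda_train(
            X, y, self.grid_exponents, self.inner_folds, self.seed
        )
        self.params = {"c": c, "gamma": gamma}
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, float)
        return self.model.predict(X).astype(int), self.model.decision_function(X)


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with cancer as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity_pct(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
    )


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC from continuous scores."""
    fpr, tpr, _ = roc_curve(y_true, scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


@dataclass
class ClassifierReport:
    """Cross-validated performance of one classifier on one spectra set."""

    classifier: str
    hyperparameters: dict
    calibration: dict[str, float]
    testing: dict[str, float]
    pooled_confusion: ConfusionMatrix
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    test_scores: np.ndarray
    test_predictions: np.ndarray
    fold_of_sample: np.ndarray

    def to_dict(self) -> dict:
        cm = self.pooled_confusion
        return {
            "classifier": self.classifier,
            "hyperparameters": self.hyperparameters,
            "calibration": self.calibration,
            "testing": self.testing,
            "pooled_confusion": {"tp": cm.tp, "fn": cm.fn, "tn": cm.tn, "fp": cm.fp},
            "pooled_testing": {
                "accuracy_pct": cm.accuracy_pct,
                "sensitivity_pct": cm.sensitivity_pct,
                "specificity_pct": cm.specificity_pct,
            },
            "auc": self.auc,
            "roc": {"fpr": self.roc_fpr.tolist(), "tpr": self.roc_tpr.tolist()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _metric_triple(cm: ConfusionMatrix) -> tuple[float, float, float]:
    return cm.accuracy_pct, cm.sensitivity_pct, cm.specificity_pct


def evaluate(
    X: np.ndarray,
    y: np.ndarray,
    classifier,
    fold_plan: FoldPlan,
) -> ClassifierReport:
    """Cross-validate a classifier over a fold plan and assemble the report.

    Per-fold calibration and testing metrics are averaged; the confusion
    matrix and the ROC/AUC are pooled over the per-fold test predictions
    (every sample is tested exactly once).
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    n = len(y)
    test_pred = np.empty(n, dtype=int)
    test_scores = np.empty(n, dtype=float)
    fold_of_sample = np.empty(n, dtype=int)
    cal_metrics, test_metrics = [], []
    hyper: dict = {}
    for fold_id, (cal, test) in enumerate(fold_plan):
        model = classifier.fit(X[cal], y[cal])
        hyper = dict(model.params)
        pred_cal, _ = model.predict(X[cal])
        pred_test, score_test = model.predict(X[test])
        test_pred[test] = pred_test
        test_scores[test] = score_test
        fold_of_sample[test] = fold_id
        cal_metrics.append(_metric_triple(confusion_from_predictions(y[cal], pred_cal)))
        test_metrics.append(_metric_triple(confusion_from_predictions(y[test], pred_test)))
    cal_mean = np.mean(cal_metrics, axis=0)
    test_mean = np.mean(test_metrics, axis=0)
    pooled = confusion_from_predictions(y, test_pred)
    fpr, tpr, auc = roc_auc(y, test_scores)
    return ClassifierReport(
        classifier=classifier.name,
        hyperparameters=hyper,
        calibration={
            "accuracy_pct": float(cal_mean[0]),
            "sensitivity_pct": float(cal_mean[1]),
            "specificity_pct": float(cal_mean[2]),
        },
        testing={
            "accuracy_pct": float(test_mean[0]),
            "sensitivity_pct": float(test_mean[1]),
            "specificity_pct": float(test_mean[2]),
        },
        pooled_confusion=pooled,
        auc=auc,
        roc_fpr=fpr,
        roc_tpr=tpr,
        test_scores=test_scores,
        test_predictions=test_pred,
        fold_of_sample=fold_of_sample,
    )


def make_classifier(name: str, seed: int = 0, **kwargs):
    """Factory for the three supported classifiers."""
    if name == "knn":
        return KNNClassifier(**kwargs)
    if name == "plsda":
        return PLSDAClassifier(**kwargs)
    if name == "svmda":
        return SVMDAClassifier(seed=seed, **kwargs)
    raise ValueError(f"unknown classifier {name!r}; expected knn | plsda | svmda")
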