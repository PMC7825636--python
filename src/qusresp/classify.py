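"""Response classification: forward SFS, LOO-CV, LDA/KNN/SVM-RBF, ROC.

Features are greedily selected by forward sequential feature selection
(SFS) with the F1 score of the responder class as the selection metric,
capped at four features to limit overfitting (~1/10 of the observations
per class).  Models are evaluated with leave-one-out cross-validation;
by default feature selection, standardization and hyperparameter choice
all run inside each training fold (``nested_selection=True``, leakage
safe).  ``nested_selection=False`` performs one global selection before
the LOO loop, emulating the simpler protocol often used in radiomics
studies; both variants are reported by the examples.

Classifier families: linear discriminant analysis (shared-covariance
Gaussian classes), k-nearest neighbours (k in {1, 3, 5}, Euclidean,
score = responder vote fraction) and an RBF-kernel SVM whose (C, gamma)
are chosen by inner cross-validated F1 over a powers-of-4 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

POSITIVE_LABEL = "R"   # F1 positive class: responder
MAX_FEATURES = 4

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-5, 16, 2))     # 2^-5 .. 2^15
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-15, 4, 2))  # 2^-15 .. 2^3


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus its hyperparameter search space."""

    family: str                                   # 'LDA' | 'KNN' | 'SVM-RBF'
    k_grid: tuple = (1, 3, 5)
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID

    def __post_init__(self):
        if self.family not in ("LDA", "KNN", "SVM-RBF"):
            raise ValueError("family must be LDA, KNN or SVM-RBF")
        if self.family == "KNN" and (not self.k_grid
                                     or any(k % 2 == 0 for k in self.k_grid)):
            raise ValueError("KNN k grid must be non-empty odd integers")
        if self.family == "SVM-RBF" and (not self.c_grid
                                         or not self.gamma_grid):
            raise ValueError("SVM grids must be non-empty")


def _fit_lda(X, y):
    """LDA fit with a ridge-regularized fallback for singular covariance."""
    est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
    try:
        est.fit(X, y)
    except np.linalg.LinAlgError:
        import warnings
        warnings.warn("singular pooled covariance: refitting LDA with "
                      "ridge shrinkage", RuntimeWarning, stacklevel=2)
        est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.05)
        est.fit(X, y)
    return est


def _score_estimator(est, X):
    """Continuous responder score: decision function or vote fraction."""
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    proba = est.predict_proba(X)
    pos = list(est.classes_).index(1)
    return np.asarray(proba[:, pos], dtype=float)


def fit_predict_lda(train_X, train_y, test_X):
    """Shared-covariance Gaussian-posterior classifier (expects
    standardized features).  Returns (scores, predicted labels)."""
    est = _fit_lda(train_X, train_y)
    return _score_estimator(est, test_X), est.predict(test_X)


def fit_predict_knn(train_X, train_y, test_X, k=5):
    """Majority vote among the k Euclidean nearest neighbours; the score
    is the responder vote fraction."""
    est = KNeighborsClassifier(n_neighbors=k).fit(train_X, train_y)
    return _score_estimator(est, test_X), est.predict(test_X)


def fit_predict_svm_rbf(train_X, train_y, test_X, C=1.0, gamma="scale"):
    """RBF-kernel SVM; the score is the signed decision-function value."""
    est = SVC(kernel="rbf", C=C, gamma=gamma).fit(train_X, train_y)
    return _score_estimator(est, test_X), est.predict(test_X)


def _stratified_folds(y, n_splits):
    """Deterministic stratified folds: round-robin per class in index
    order (no shuffling, so selection is reproducible bit-for-bit)."""
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        fold[idx] = np.arange(len(idx)) % n_splits
    return [(np.nonzero(fold != k)[0], np.nonzero(fold == k)[0])
            for k in range(n_splits)]


def _standardize(Xtr, Xte):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _f1(y_true, y_pred):
    tp = np.sum((y_pred == 1) & (y_true == 1))
    fp = np.sum((y_pred == 1) & (y_true == 0))
    fn = np.sum((y_pred == 0) & (y_true == 1))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def _lda_predict_fast(Xtr, ytr, Xte):
    """Closed-form shared-covariance LDA (tiny-ridge stabilized)."""
    X0, X1 = Xtr[ytr == 0], Xtr[ytr == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    Xc = np.concatenate([X0 - mu0, X1 - mu1])
    d = Xtr.shape[1]
    cov = Xc.T @ Xc / max(1, len(Xtr) - 2) + 1e-8 * np.eye(d)
    w = np.linalg.solve(cov, mu1 - mu0)
    b = -0.5 * (mu0 + mu1) @ w + np.log(len(X1) / len(X0))
    return (Xte @ w + b > 0).astype(int)


def _knn_predict_fast(Xtr, ytr, Xte, k=5):
    d2 = ((Xte[:, None, :] - Xtr[None, :, :]) ** 2).sum(axis=-1)
    k = min(k, len(ytr))
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = ytr[order].mean(axis=1)
    return (votes > 0.5).astype(int)


def _fast_predictor(family, **hp):
    if family == "LDA":
        return _lda_predict_fast
    if family == "KNN":
        k = hp.get("k", 5)
        return lambda Xtr, ytr, Xte: _knn_predict_fast(Xtr, ytr, Xte, k)
    if family == "SVM-RBF":
        C, gamma = hp.get("C", 1.0), hp.get("gamma", "scale")

        def _svm(Xtr, ytr, Xte):
            est = SVC(kernel="rbf", C=C, gamma=gamma).fit(Xtr, ytr)
            return est.predict(Xte)
        return _svm
    raise ValueError(family)


def _inner_f1(X, y, predictor, n_splits=3):
    """Mean responder-class F1 over deterministic stratified folds, with
    per-fold standardization fit on the fold's training part."""
    n_splits = min(n_splits, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("need >= 2 patients per class for inner validation")
    scores = []
    for tr, va in _stratified_folds(y, n_splits):
        Xtr, Xva = _standardize(X[tr], X[va])
        pred = predictor(Xtr, y[tr], Xva)
        scores.append(_f1(y[va], np.asarray(pred)))
    return float(np.mean(scores))


def sfs_select(X, y, spec: ClassifierSpec, max_features=MAX_FEATURES,
               inner_splits=3):
    """Forward sequential feature selection with an inner-CV F1 metric.

    Greedily grows the subset: at each step the candidate column (in
    column order) whose addition maximizes inner-validation F1 is added;
    ties break to the lowest column index.  Exactly
    ``min(max_features, n_columns)`` indices are returned, in selection
    order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2 or int(np.bincount(y).min()) < 2:
        raise ValueError("training data must contain >= 2 patients per class")
    n_cols = X.shape[1]
    selected = []
    remaining = list(range(n_cols))
    predictor = _fast_predictor(spec.family)
    while remaining and len(selected) < max_features:
        best_score, best_col = -np.inf, None
        for col in remaining:
            cols = selected + [col]
            score = _inner_f1(X[:, cols], y, predictor, inner_splits)
            if score > best_score:
                best_score, best_col = score, col
        selected.append(best_col)
        remaining.remove(best_col)
    return selected


def grid_search_svm(X, y, c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                    inner_splits=3):
    """Exhaustive (C, gamma) grid search by inner-CV F1 (first-best ties)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    best = (-np.inf, None, None)
    for C in c_grid:
        for gamma in gamma_grid:
            score = _inner_f1(X, y, _fast_predictor("SVM-RBF", C=C,
                                                    gamma=gamma),
                              inner_splits)
            if score > best[0]:
                best = (score, C, gamma)
    return {"C": best[1], "gamma": best[2], "f1": best[0]}


def select_knn_k(X, y, k_grid=(1, 3, 5), inner_splits=3):
    """Choose k among the grid by inner-CV F1 (first-best ties)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    best = (-np.inf, None)
    for k in k_grid:
        score = _inner_f1(X, y, _fast_predictor("KNN", k=k), inner_splits)
        if score > best[0]:
            best = (score, k)
    return best[1]


def _tune_and_fit(spec, X, y):
    """Hyperparameter choice on the training data, then final fit."""
    if spec.family == "LDA":
        return _fit_lda(X, y), {}
    if spec.family == "KNN":
        k = select_knn_k(X, y, spec.k_grid)
        return KNeighborsClassifier(n_neighbors=k).fit(X, y), {"k": k}
    res = grid_search_svm(X, y, spec.c_grid, spec.gamma_grid)
    hp = {"C": res["C"], "gamma": res["gamma"]}
    return SVC(kernel="rbf", **hp).fit(X, y), hp


@dataclass
class CVResult:
    """Pooled LOO-CV predictions and ROC performance."""

    y_true: np.ndarray
    scores: np.ndarray
    predictions: np.ndarray
    selected_features: list
    metrics: dict
    spec: ClassifierSpec = None
    feature_names: list = field(default_factory=list)


def roc_metrics(y_true, scores, predictions):
    """Sensitivity, specificity, accuracy, AUC, PPV and NPV (fractions).

    Confusion counts use the classifier's native decision threshold
    (``predictions``); the AUC is computed from the continuous scores via
    the rank (Mann-Whitney) formulation with half credit for ties.
    """
    y_true = np.asarray(y_true).astype(int)
    predictions = np.asarray(predictions).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC metrics need both classes present")
    tp = int(np.sum((predictions == 1) & (y_true == 1)))
    tn = int(np.sum((predictions == 0) & (y_true == 0)))
    fp = int(np.sum((predictions == 1) & (y_true == 0)))
    fn = int(np.sum((predictions == 0) & (y_true == 1)))
    n = len(y_true)
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / n,
        "auc": float(roc_auc_score(y_true, scores)),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }


def _split_table(table):
    if isinstance(table, pd.DataFrame):
        if "label" not in table.columns:
            raise ValueError("feature table must carry a 'label' column")
        y = (table["label"] == POSITIVE_LABEL).to_numpy().astype(int)
        X = table.drop(columns="label").to_numpy(dtype=float)
        names = [c for c in table.columns if c != "label"]
        return X, y, names
    X, y = table
    return np.asarray(X, dtype=float), np.asarray(y).astype(int), \
        [f"f{i}" for i in range(np.asarray(X).shape[1])]


def loocv_evaluate(table, spec: ClassifierSpec,
                   nested_selection=True, max_features=MAX_FEATURES,
                   select=True) -> CVResult:
    """Leave-one-out cross-validation of one classifier family.

    Per fold: (optionally nested) SFS on the training portion, z-score
    standardization fit on the training portion only, hyperparameter
    choice by inner CV, classifier fit and scoring of the held-out
    patient.  Metrics are computed from the pooled predictions; the AUC
    from the pooled continuous scores.
    """
    X, y, names = _split_table(table)
    n = len(y)
    if n < 4 or len(np.unique(y)) < 2:
        raise ValueError("need n >= 4 with both classes present")
    global_cols = None
    if select and not nested_selection:
        global_cols = sfs_select(X, y, spec, max_features)
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    selected_per_fold = []
    for i in range(n):
        tr = np.setdiff1d(np.arange(n), [i])
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {i}: single-class training data")
        if select:
            cols = sfs_select(X[tr], y[tr], spec, max_features) \
                if nested_selection else global_cols
        else:
            cols = list(range(X.shape[1]))
        scaler = StandardScaler().fit(X[np.ix_(tr, cols)])
        Xtr = scaler.transform(X[np.ix_(tr, cols)])
        Xte = scaler.transform(X[i:i + 1, cols])
        est, _ = _tune_and_fit(spec, Xtr, y[tr])
        scores[i] = _score_estimator(est, Xte)[0]
        preds[i] = int(est.predict(Xte)[0])
        selected_per_fold.append([names[c] for c in cols])
    metrics = roc_metrics(y, scores, preds)
    return CVResult(y_true=y, scores=scores, predictions=preds,
                    selected_features=selected_per_fold, metrics=metrics,
                    spec=spec, feature_names=names)
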