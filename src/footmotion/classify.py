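"""Feature compression (PCA) and classification with evaluation reports.

The 34 features mix units (g, deg/s, radians), so they are standardized to
zero mean and unit variance before the singular-value decomposition; the
retained dimension is the smallest one whose cumulative explained variance
reaches the configured fraction.

Classification is a soft-margin SVM whose penalty C, kernel width gamma and
kernel family are selected by exhaustive grid search under stratified k-fold
cross-validation (ties broken toward smaller C, then smaller gamma, then the
kernel order linear, poly, rbf, sigmoid).  K-nearest-neighbours and a depth-
limited decision tree serve as baselines.  Evaluation reports per-class
precision (also exposed under the alias "accuracy"), recall and F1, macro
averages, overall accuracy and the confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .config import DEFAULT_SVM_GRID
from .recording import ValidationError

__all__ = [
    "PCAModel",
    "ClassifierModel",
    "EvaluationReport",
    "fit_pca",
    "transform_pca",
    "inverse_transform_pca",
    "split_dataset",
    "train_classifier",
    "evaluate",
    "f1_from_precision_recall",
    "macro_average",
]

KERNEL_ORDER = ("linear", "poly", "rbf", "sigmoid")


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_average(per_class_values: Sequence[float]) -> float:
    """Unweighted mean over classes."""
    return float(np.mean(per_class_values))


# --------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Standardization constants plus the fitted orthonormal loadings."""

    mean_: np.ndarray
    scale_: np.ndarray
    components_: np.ndarray          # (r, m) retained loadings
    singular_values_: np.ndarray     # all min(n, m) singular values
    explained_variance_ratio_: np.ndarray  # all components, sums to 1
    n_components: int
    feature_names: tuple[str, ...] | None = None

    @property
    def cumulative_explained_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio_)


def _standardize(model: PCAModel, X: np.ndarray) -> np.ndarray:
    return (X - model.mean_) / model.scale_


def fit_pca(F: pd.DataFrame | np.ndarray, variance_kept: float = 0.95) -> PCAModel:
    """Standardize columns, decompose, and retain the smallest dimension
    whose cumulative explained variance reaches ``variance_kept``.

    Zero-variance columns are centred but not scaled.  With
    ``variance_kept = 1`` the retained dimension equals the rank of the
    centred matrix.
    """
    if not 0 < variance_kept <= 1:
        raise ValidationError("variance_kept must lie in (0, 1]")
    names = tuple(F.columns) if isinstance(F, pd.DataFrame) else None
    X = np.asarray(F, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("PCA needs a 2-D matrix with at least 2 rows")

    scaler = StandardScaler().fit(X)  # population variance; zero-var cols keep scale 1
    Z = scaler.transform(X)
    pca = PCA(svd_solver="full").fit(Z)

    ratios = pca.explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    reached = np.flatnonzero(cumulative >= variance_kept - 1e-12)
    if len(reached):
        r = int(reached[0]) + 1
    else:  # numerically all variance needed: keep every non-degenerate component
        r = int(np.sum(pca.singular_values_ > 1e-12))
    return PCAModel(
        mean_=scaler.mean_.copy(),
        scale_=scaler.scale_.copy(),
        components_=pca.components_[:r].copy(),
        singular_values_=pca.singular_values_.copy(),
        explained_variance_ratio_=ratios.copy(),
        n_components=r,
        feature_names=names,
    )


def transform_pca(model: PCAModel, F: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Project (standardized) rows onto the retained loadings: an (n, r) score matrix."""
    X = np.asarray(F, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.mean_.shape[0]:
        raise ValidationError(
            f"column count {X.shape[1]} does not match the fitted model "
            f"({model.mean_.shape[0]})"
        )
    return _standardize(model, X) @ model.components_.T


def inverse_transform_pca(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Map scores back to the standardized feature space."""
    return np.asarray(scores) @ model.components_


# --------------------------------------------------------------------------
# Splitting and training

def split_dataset(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    fraction: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test indices at ``fraction`` training share.

    The training size is ``floor(fraction * n)``, allocated across classes
    by largest remainder; deterministic per seed.  Returns (train_idx,
    test_idx) into the rows of ``X``.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("both classes must be present to split")
    if np.min(counts) < 2:
        raise ValidationError("every class needs at least 2 members to split")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=fraction, stratify=y, random_state=seed, shuffle=True
    )
    return np.sort(train_idx), np.sort(test_idx)


@dataclass
class ClassifierModel:
    """A fitted classifier plus the hyperparameters that won the grid search."""

    algorithm: str
    params: dict
    estimator: object
    cv_accuracy: float
    cv_results: list[dict] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.decision_function(np.asarray(X, dtype=float))


def _make_svc(params: dict) -> SVC:
    # tight optimizer tolerance: problems here are small (hundreds of rows)
    # and the decision function is contract-tested against an exact QP
    return SVC(C=params["C"], gamma=params["gamma"], kernel=params["kernel"], tol=1e-8)


def train_classifier(
    X: np.ndarray,
    y: Sequence,
    algorithm: str = "svm",
    grid: dict | None = None,
    folds: int = 3,
    seed: int = 0,
    knn_neighbors: int = 4,
    tree_min_samples_split: int = 3,
    tree_max_depth: int = 6,
) -> ClassifierModel:
    """Grid-search (SVM) or fixed-parameter (baselines) training.

    The SVM grid is scanned exhaustively by mean stratified-CV accuracy;
    ties break toward smaller C, then smaller gamma, then kernel order.
    The winner is refit on the full training set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("training set must contain both classes")
    if np.min(counts) < folds:
        raise ValidationError(
            f"every class needs at least {folds} members for {folds}-fold CV"
        )

    if algorithm == "knn":
        est = KNeighborsClassifier(n_neighbors=knn_neighbors).fit(X, y)
        params = {"n_neighbors": knn_neighbors}
        acc = _cv_accuracy(lambda: KNeighborsClassifier(n_neighbors=knn_neighbors),
                           X, y, folds, seed)
        return ClassifierModel("knn", params, est, acc)
    if algorithm == "tree":
        def make_tree():
            return DecisionTreeClassifier(
                min_samples_split=tree_min_samples_split,
                max_depth=tree_max_depth,
                random_state=seed,
            )
        est = make_tree().fit(X, y)
        params = {"min_samples_split": tree_min_samples_split, "max_depth": tree_max_depth}
        return ClassifierModel("tree", params, est, _cv_accuracy(make_tree, X, y, folds, seed))
    if algorithm != "svm":
        raise ValidationError(f"unknown algorithm {algorithm!r}")

    grid = grid or {k: list(v) for k, v in DEFAULT_SVM_GRID.items()}
    kernels = sorted(grid["kernel"], key=KERNEL_ORDER.index)
    best: tuple[float, dict] | None = None
    results = []
    # iteration order C asc -> gamma asc -> kernel order realizes the tie-break
    for C, gamma, kernel in product(sorted(grid["C"]), sorted(grid["gamma"]), kernels):
        params = {"C": float(C), "gamma": float(gamma), "kernel": kernel}
        acc = _cv_accuracy(lambda: _make_svc(params), X, y, folds, seed)
        results.append({**params, "cv_accuracy": acc})
        if best is None or acc > best[0] + 1e-12:
            best = (acc, params)
    assert best is not None
    est = _make_svc(best[1]).fit(X, y)
    return ClassifierModel("svm", best[1], est, best[0], results)


def _cv_accuracy(factory, X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        est = factory().fit(X[train], y[train])
        accs.append(float(np.mean(est.predict(X[test]) == y[test])))
    return float(np.mean(accs))


# --------------------------------------------------------------------------
# Evaluation

@dataclass
class EvaluationReport:
    """Per-class precision/recall/F1, macro averages and the confusion matrix.

    Per-class precision is also exposed under the alias ``accuracy`` (the
    name some reports print for that column).  ``confusion[i][j]`` counts
    samples of true class ``labels[i]`` predicted as ``labels[j]``.
    """

    labels: list[str]
    confusion: list[list[int]]
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    overall_accuracy: float
    algorithm: str = ""
    params: dict = field(default_factory=dict)
    seed: int | None = None
    stage_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "confusion": self.confusion,
            "per_class": self.per_class,
            "macro": self.macro,
            "overall_accuracy": self.overall_accuracy,
            "algorithm": self.algorithm,
            "params": self.params,
            "seed": self.seed,
            "stage_counts": self.stage_counts,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def evaluate(
    model: ClassifierModel,
    X: np.ndarray,
    y: Sequence,
    seed: int | None = None,
) -> EvaluationReport:
    """Confusion matrix and precision/recall/F1 report on a held-out set."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValidationError("test set is empty")
    labels = sorted(np.unique(y).tolist())
    if len(labels) < 2:
        raise ValidationError("test set must contain both classes")
    pred = model.predict(X)

    index = {lab: i for i, lab in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for yt, yp in zip(y, pred):
        confusion[index[yt], index.get(yp, 0)] += 1

    per_class: dict[str, dict[str, float]] = {}
    for i, lab in enumerate(labels):
        tp = confusion[i, i]
        predicted = confusion[:, i].sum()
        actual = confusion[i, :].sum()
        precision = float(tp / predicted) if predicted else 0.0
        recall = float(tp / actual) if actual else 0.0
        per_class[lab] = {
            "precision": precision,
            "accuracy": precision,  # column alias
            "recall": recall,
            "f1": f1_from_precision_recall(precision, recall),
        }
    macro = {
        key: macro_average([per_class[lab][key] for lab in labels])
        for key in ("precision", "recall", "f1")
    }
    return EvaluationReport(
        labels=labels,
        confusion=confusion.tolist(),
        per_class=per_class,
        macro=macro,
        overall_accuracy=float(np.trace(confusion) / confusion.sum()),
        algorithm=model.algorithm,
        params=model.params,
        seed=seed,
    )
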