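"""Binary nuclear/non-nuclear SVM with RBF kernel and grid-tuned (c, gamma).

The optimizer itself is scikit-learn's libsvm wrapper; this module owns the
seeded stratified fold assignment, the grid search, deterministic
tie-breaking (smaller c, then smaller gamma) and probability outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .signatures import CLASSES, NUCLEAR

#: libsvm-guide style grid: c = 2^-5..2^15, gamma = 2^-15..2^3, steps of 4x.
DEFAULT_GRID = [
    (2.0**log_c, 2.0**log_g)
    for log_c in range(-5, 16, 2)
    for log_g in range(-15, 4, 2)
]


@dataclass
class TrainedClassifier:
    cost: float
    gamma: float
    feature_mode: str
    feature_dimension: int
    classes: tuple[str, ...]
    tuning_record: list[tuple[float, float, float]]  # (c, gamma, mean CV accuracy)
    seed: int
    _svc: SVC = field(repr=False, default=None)


def _validate_labels(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray(labels)
    present = set(y.tolist())
    unknown = present - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    if len(present) < 2:
        raise ValueError("training data must contain both classes")
    return y


def tune_and_train(
    features: np.ndarray,
    labels: Sequence[str],
    grid: Sequence[tuple[float, float]] | None = None,
    folds: int = 5,
    seed: int = 0,
    feature_mode: str = "plsi_topics",
) -> TrainedClassifier:
    """Grid-search (c, gamma) by stratified CV accuracy, then refit on all data.

    Ties in mean CV accuracy resolve toward smaller c, then smaller gamma,
    so the result is deterministic given the seed.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    y = _validate_labels(labels)
    if len(y) != X.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    grid = list(DEFAULT_GRID if grid is None else grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    class_counts = {cls: int(np.sum(y == cls)) for cls in set(y.tolist())}
    if folds > min(class_counts.values()):
        raise ValueError(
            f"folds={folds} exceeds minority class size {min(class_counts.values())}"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X, y))
    record: list[tuple[float, float, float]] = []
    best: tuple[float, float, float] | None = None  # (-acc, c, gamma)
    for c, g in grid:
        correct = 0
        for train_idx, test_idx in splits:
            svc = SVC(kernel="rbf", C=c, gamma=g, random_state=seed)
            svc.fit(X[train_idx], y[train_idx])
            correct += int(np.sum(svc.predict(X[test_idx]) == y[test_idx]))
        acc = correct / len(y)
        record.append((c, g, acc))
        key = (-acc, c, g)
        if best is None or key < best:
            best = key
    _, c_best, g_best = best
    with warnings.catch_warnings():
        # probability=True is libsvm's pairwise-coupling estimator, which is
        # the contract here; silence scikit-learn's deprecation advertisement.
        warnings.filterwarnings("ignore", category=FutureWarning)
        svc = SVC(kernel="rbf", C=c_best, gamma=g_best, probability=True, random_state=seed)
        svc.fit(X, y)
    return TrainedClassifier(
        cost=c_best,
        gamma=g_best,
        feature_mode=feature_mode,
        feature_dimension=X.shape[1],
        classes=tuple(svc.classes_.tolist()),
        tuning_record=record,
        seed=seed,
        _svc=svc,
    )


def predict_localization(clf: TrainedClassifier, vector: np.ndarray) -> tuple[str, float]:
    """Predicted class with its probability (>= 0.5 by binary argmax)."""
    v = np.asarray(vector, dtype=float).ravel()
    if v.shape[0] != clf.feature_dimension:
        raise ValueError(
            f"vector dimension {v.shape[0]} != classifier dimension {clf.feature_dimension}"
        )
    proba = clf._svc.predict_proba(v[None, :])[0]
    idx = int(np.argmax(proba))
    return clf.classes[idx], float(proba[idx])


def predict_proba_matrix(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Class-probability rows for a feature matrix, columns in ``clf.classes`` order."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != clf.feature_dimension:
        raise ValueError(
            f"matrix dimension {X.shape[1]} != classifier dimension {clf.feature_dimension}"
        )
    return clf._svc.predict_proba(X)
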