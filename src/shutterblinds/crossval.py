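"""Fine kNN (k=1, Manhattan) and tenfold cross-validation with pooled confusion.

Every sample is tested exactly once: the data are split into seeded
(by default stratified) folds, each fold is predicted by a 1-nearest-
neighbour model trained on the remaining folds under the city-block
distance d(a, b) = sum_l |a_l - b_l|, and the test predictions of all
folds are pooled into a single K x K confusion matrix, the form in which
the results tables of this kind of study are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ValidationError

__all__ = ["CVSpec", "ConfusionMatrix", "make_folds", "knn_predict", "cross_validate"]


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation layout: fold count, shuffling seed, stratification."""

    n_folds: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError(f"n_folds must be >= 2, got {self.n_folds}")


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = self.counts.shape[0]
        if self.counts.ndim != 2 or self.counts.shape[1] != k:
            raise ValidationError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("confusion matrix counts must be nonnegative")
        if not self.labels:
            self.labels = tuple(f"C{i}" for i in range(k))
        elif len(self.labels) != k:
            raise ValidationError("label count does not match matrix size")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="true\\pred")

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int, labels=()) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(counts, (y_true, y_pred), 1)
        return cls(counts, tuple(labels))


def make_folds(y, cv: CVSpec) -> list[np.ndarray]:
    """Seeded fold partition: list of test-index arrays, one per fold.

    Stratified folds keep per-fold class counts within 1 of proportional;
    a class smaller than the fold count cannot be stratified and raises.
    """
    y = np.asarray(y, dtype=int)
    if len(y) < cv.n_folds:
        raise ValidationError(f"{len(y)} samples cannot form {cv.n_folds} folds")
    if cv.stratified:
        smallest = np.bincount(y).min()
        if smallest < cv.n_folds:
            raise ValidationError(
                f"smallest class has {smallest} members < {cv.n_folds} folds; "
                "reduce n_folds or use stratified=False"
            )
        splitter = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    else:
        splitter = KFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    return [test for _, test in splitter.split(np.zeros(len(y)), y)]


def knn_predict(train_X, train_y, test_X, k: int = 1, metric: str = "manhattan") -> np.ndarray:
    """Predict test labels by k-nearest-neighbour vote (default fine kNN, k=1).

    Distance ties are broken by the smaller training-row index; label ties
    at k > 1 by the smaller label.  Deterministic.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    test_X = np.asarray(test_X, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=int)
    if train_X.ndim != 2 or test_X.ndim != 2 or train_X.shape[1] != test_X.shape[1]:
        raise ValidationError(
            f"dimension mismatch: train {train_X.shape} vs test {test_X.shape}"
        )
    if len(train_X) == 0:
        raise ValidationError("empty training set")
    if k < 1 or k > len(train_X):
        raise ValidationError(f"k={k} outside [1, {len(train_X)}]")
    if metric not in ("manhattan", "cityblock"):
        raise ValidationError(f"unsupported metric {metric!r}")

    dist = cdist(test_X, train_X, metric="cityblock")
    if k == 1:
        # np.argmin returns the first (lowest-index) minimiser: the tie rule.
        return train_y[np.argmin(dist, axis=1)]
    preds = np.empty(len(test_X), dtype=int)
    for i, row in enumerate(dist):
        nearest = np.lexsort((np.arange(len(row)), row))[:k]
        votes = np.bincount(train_y[nearest])
        preds[i] = int(np.argmax(votes))
    return preds


def cross_validate(
    X,
    y,
    cv: CVSpec,
    k: int = 1,
    metric: str = "manhattan",
    labels=(),
    folds: list[np.ndarray] | None = None,
) -> tuple[ConfusionMatrix, np.ndarray]:
    """k-fold CV of the fine kNN, pooling test predictions across folds.

    Returns the pooled confusion matrix and the per-fold accuracies.
    ``folds`` may be precomputed (e.g. to reuse one partition across many
    candidate feature subsets); otherwise they derive from ``cv``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    n_classes = int(y.max()) + 1
    if folds is None:
        folds = make_folds(y, cv)
    y_pred = np.empty(len(y), dtype=int)
    fold_acc = np.empty(len(folds))
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        pred = knn_predict(X[train_mask], y[train_mask], X[test_idx], k=k, metric=metric)
        y_pred[test_idx] = pred
        fold_acc[f] = float(np.mean(pred == y[test_idx]))
    cm = ConfusionMatrix.from_predictions(y, y_pred, n_classes, labels)
    return cm, fold_acc
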