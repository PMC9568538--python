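"""Feature normalization, NCA relevance ranking, and iterative prefix selection.

The selector is the feature-selection variant of neighborhood component
analysis (NCA): each feature l carries a nonnegative weight w_l, distances
are weighted city-block d_w(a, b) = sum_l w_l^2 |a_l - b_l|, and sample i
softly selects each reference j != i with probability

    p_ij = exp(-d_w(x_i, x_j) / sigma) / sum_{k != i} exp(-d_w(x_i, x_k) / sigma).

The objective maximised by full-batch gradient ascent from w = 1 is the
expected leave-one-out correct-classification probability minus an L2
penalty, F(w) = sum_i sum_{j in class(i)} p_ij - lambda * sum_l w_l^2.
Features are then ranked by w^2 descending.

The iterative stage (INCA) evaluates every prefix of that ranking whose
length lies in a given range, scoring each with the misclassification rate
of the downstream fine kNN under one fixed cross-validation partition, and
keeps the shortest best-scoring prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy.spatial.distance import cdist

from .crossval import CVSpec, cross_validate, make_folds
from .errors import ValidationError

__all__ = [
    "NCARanking",
    "SelectionResult",
    "minmax_normalize",
    "apply_minmax",
    "nca_rank",
    "candidate_lengths",
    "inca_select",
    "inca_select_no_leakage",
]


def minmax_normalize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map every column to [0, 1] by (x - min) / (max - min).

    Constant columns map to 0.  Returns (normalized, mins, maxs) so the
    fitted transform can be reapplied to held-out rows.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.size == 0:
        raise ValidationError(f"expected a nonempty 2-D matrix, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValidationError("matrix contains non-finite values")
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    return apply_minmax(X, mins, maxs), mins, maxs


def apply_minmax(X: np.ndarray, mins: np.ndarray, maxs: np.ndarray) -> np.ndarray:
    """Apply a fitted min-max transform; zero-range columns map to 0."""
    span = maxs - mins
    safe = np.where(span == 0, 1.0, span)
    out = (np.asarray(X, dtype=np.float64) - mins) / safe
    out[:, span == 0] = 0.0
    return out


@dataclass(frozen=True)
class NCARanking:
    """Per-feature relevance scores (w^2) and the descending-relevance order."""

    weights: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        if sorted(self.order.tolist()) != list(range(len(self.weights))):
            raise ValidationError("order is not a permutation of the features")


def _weighted_cityblock(Xw: np.ndarray) -> np.ndarray:
    return cdist(Xw, Xw, metric="cityblock")


def _selection_probs(d: np.ndarray, sigma: float) -> np.ndarray:
    """Row-stochastic soft-neighbour matrix p_ij from a distance matrix."""
    logits = -d / sigma
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _objective_and_coeffs(
    d: np.ndarray, same: np.ndarray, sigma: float
) -> tuple[float, np.ndarray]:
    """Unpenalised objective sum_i p_i and the pair-coefficient matrix C.

    C_ij = p_i * p_ij - same_ij * p_ij appears in the gradient
    dF/dw_l = (2 w_l / sigma) * sum_ij C_ij |x_il - x_jl| - 2 lambda w_l.
    """
    p = _selection_probs(d, sigma)
    p_i = (p * same).sum(axis=1)
    C = p * (p_i[:, None] - same)
    return float(p_i.sum()), C


def _pairwise_feature_grad(X: np.ndarray, C: np.ndarray, chunk: int = 256) -> np.ndarray:
    """g_l = sum_ij C_ij |x_il - x_jl|, chunked over features to bound memory."""
    n, d = X.shape
    g = np.empty(d)
    for start in range(0, d, chunk):
        cols = X[:, start : start + chunk]
        Z = np.abs(cols[:, None, :] - cols[None, :, :])
        g[start : start + chunk] = np.tensordot(C, Z, axes=([0, 1], [0, 1]))
    return g


def nca_rank(
    X: np.ndarray,
    y: np.ndarray,
    sigma: float = 1.0,
    reg: float | None = None,
    n_iter: int = 100,
    learning_rate: float = 0.1,
    seed: int = 0,
) -> NCARanking:
    """Learn per-feature NCA relevance weights and rank features by them.

    Full-batch gradient ascent from w = 1 for ``n_iter`` iterations; a step
    that decreases the penalised objective is rejected and the learning rate
    halved.  ``reg`` (lambda) defaults to 1/N.  The procedure is
    deterministic; ``seed`` is accepted for interface uniformity and
    reserved for stochastic variants.  Ranking ties break toward the lower
    feature index.
    """
    del seed  # deterministic full-batch ascent
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValidationError("X must be 2-D with one label per row")
    if not np.isfinite(X).all():
        raise ValidationError("X contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValidationError("NCA requires at least two classes")
    n, d = X.shape
    lam = (1.0 / n) if reg is None else float(reg)
    same = (y[:, None] == y[None, :]).astype(np.float64)
    np.fill_diagonal(same, 0.0)

    w = np.ones(d)
    lr = float(learning_rate)

    def penalised(wv: np.ndarray) -> tuple[float, np.ndarray]:
        dist = _weighted_cityblock(X * (wv**2))
        raw, C = _objective_and_coeffs(dist, same, sigma)
        return raw - lam * float(wv @ wv), C

    f_cur, C = penalised(w)
    for _ in range(n_iter):
        grad = (2.0 * w / sigma) * _pairwise_feature_grad(X, C) - 2.0 * lam * w
        w_new = w + lr * grad
        f_new, C_new = penalised(w_new)
        if f_new < f_cur:
            lr *= 0.5  # reject the step, keep the current iterate
            continue
        w, f_cur, C = w_new, f_new, C_new

    relevance = w**2
    order = np.argsort(-relevance, kind="stable")
    return NCARanking(relevance, order)


@dataclass
class SelectionResult:
    """Loss curve over candidate prefix lengths and the winning subset."""

    lengths: np.ndarray
    losses: np.ndarray
    best_length: int
    selected: np.ndarray
    mode: str = "faithful"
    seed: int = 0

    @property
    def best_loss(self) -> float:
        return float(self.losses[int(np.flatnonzero(self.lengths == self.best_length)[0])])

    def to_dict(self) -> dict:
        return {
            "lengths": self.lengths.tolist(),
            "losses": self.losses.tolist(),
            "best_length": int(self.best_length),
            "selected_indexes": self.selected.tolist(),
            "mode": self.mode,
            "seed": int(self.seed),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def candidate_lengths(lo: int, hi: int, n_features: int, step: int = 1) -> np.ndarray:
    """The prefix lengths the iterative loop evaluates: lo..hi clipped to D."""
    if lo < 1:
        raise ValidationError(f"lo must be >= 1, got {lo}")
    if step < 1:
        raise ValidationError(f"step must be >= 1, got {step}")
    lo_eff = min(lo, n_features)
    hi_eff = min(hi, n_features)
    lengths = np.arange(lo_eff, hi_eff + 1, step)
    if lengths.size == 0:
        raise ValidationError(f"empty candidate range [{lo}, {hi}] for D={n_features}")
    return lengths


def inca_select(
    X: np.ndarray,
    y: np.ndarray,
    ranking: NCARanking,
    lo: int = 100,
    hi: int = 1000,
    cv: CVSpec = CVSpec(),
    step: int = 1,
    k: int = 1,
    metric: str = "manhattan",
) -> SelectionResult:
    """Evaluate every ranked-prefix length in [lo, hi] and keep the best.

    Each candidate prefix is scored by the misclassification rate of the
    k=1 Manhattan kNN under one fixed CV partition (the same folds for every
    length, so losses are comparable).  Ties go to the shortest prefix.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    lengths = candidate_lengths(lo, hi, X.shape[1], step)
    folds = make_folds(y, cv)
    losses = np.empty(len(lengths))
    for i, l in enumerate(lengths):
        cm, _ = cross_validate(
            X[:, ranking.order[:l]], y, cv, k=k, metric=metric, folds=folds
        )
        losses[i] = 1.0 - cm.accuracy
    best_i = int(np.argmin(losses))  # first minimiser -> smallest length
    best_length = int(lengths[best_i])
    return SelectionResult(
        lengths, losses, best_length, ranking.order[:best_length].copy(),
        mode="faithful", seed=cv.seed,
    )


def inca_select_no_leakage(
    X_raw: np.ndarray,
    y: np.ndarray,
    lo: int,
    hi: int,
    cv: CVSpec = CVSpec(),
    step: int = 1,
    k: int = 1,
    metric: str = "manhattan",
    nca_params: dict | None = None,
) -> SelectionResult:
    """Strict variant: normalization and ranking are refit inside each fold.

    The default mode normalizes and ranks once on the full matrix before
    cross-validation, mirroring the pipeline order this architecture
    prescribes; that lets test-fold rows influence the scaler and the
    ranking.  Here each fold's min-max transform and NCA ranking are fitted
    on its training rows only, giving honest generalization estimates.  The
    reported ``selected`` subset is the best-length prefix of a final
    full-data ranking (the loss curve, not the subset, is fold-honest).
    """
    X_raw = np.asarray(X_raw, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    params = nca_params or {}
    lengths = candidate_lengths(lo, hi, X_raw.shape[1], step)
    folds = make_folds(y, cv)
    errors = np.zeros(len(lengths))
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        Xtr, mins, maxs = minmax_normalize(X_raw[train_mask])
        Xte = apply_minmax(X_raw[test_idx], mins, maxs)
        rk = nca_rank(Xtr, y[train_mask], **params)
        for i, l in enumerate(lengths):
            from .crossval import knn_predict

            pred = knn_predict(
                Xtr[:, rk.order[:l]], y[train_mask], Xte[:, rk.order[:l]],
                k=k, metric=metric,
            )
            errors[i] += int(np.sum(pred != y[test_idx]))
    losses = errors / len(y)
    best_i = int(np.argmin(losses))
    best_length = int(lengths[best_i])
    Xn, _, _ = minmax_normalize(X_raw)
    final_rank = nca_rank(Xn, y, **params)
    return SelectionResult(
        lengths, losses, best_length, final_rank.order[:best_length].copy(),
        mode="no_leakage", seed=cv.seed,
    )
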