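"""Min-max normalization, NCA relevance ranking, and iterative prefix selection."""

import numpy as np
import pytest

from shutterblinds import (
    CVSpec,
    ValidationError,
    candidate_lengths,
    cross_validate,
    inca_select,
    inca_select_no_leakage,
    make_folds,
    minmax_normalize,
    nca_rank,
)
from shutterblinds.crossval import knn_predict


class TestMinMaxNormalize:
    def test_closed_form_column(self):
        Xn, mins, maxs = minmax_normalize(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(Xn.ravel(), [0, 0.5, 1])
        assert mins[0] == 2 and maxs[0] == 6

    def test_constant_column_maps_to_zero(self):
        Xn, _, _ = minmax_normalize(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert np.all(Xn[:, 0] == 0)

    def test_idempotent_on_unit_range_columns(self, rng):
        X = rng.uniform(size=(10, 4))
        X[0] = 0.0
        X[1] = 1.0  # force each column to span [0, 1]
        Xn, _, _ = minmax_normalize(X)
        Xnn, _, _ = minmax_normalize(Xn)
        assert np.allclose(Xn, Xnn)
        assert np.allclose(Xn, X)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            minmax_normalize(np.empty((0, 3)))


def _planted_problem(seed, n=200, d=20, n_informative=2):
    """Two classes separated on the informative pair; the rest pure noise.

    The class means on the informative features are 0.2 and 0.8 with
    sd 0.05, so a nearest-centroid rule on those features alone is
    essentially Bayes-perfect (checked by test_planted_problem_is_separable).
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.uniform(size=(n, d))
    means = np.where(y[:, None] == 0, 0.2, 0.8)
    X[:, :n_informative] = rng.normal(means, 0.05, (n, n_informative))
    perm = rng.permutation(n)
    return X[perm], y[perm]


def test_planted_problem_is_separable():
    """Nearest-centroid on the informative pair is a ~perfect oracle."""
    X, y = _planted_problem(seed=0)
    c0 = X[y == 0, :2].mean(axis=0)
    c1 = X[y == 1, :2].mean(axis=0)
    pred = (
        np.abs(X[:, :2] - c1).sum(axis=1) < np.abs(X[:, :2] - c0).sum(axis=1)
    ).astype(int)
    assert np.mean(pred == y) >= 0.99


class TestNCARank:
    def test_duplicate_columns_get_equal_weights(self):
        X, y = _planted_problem(seed=1, d=6)
        X = np.column_stack([X, X[:, 0]])  # clone an informative column
        Xn, _, _ = minmax_normalize(X)
        rk = nca_rank(Xn, y)
        assert rk.weights[0] == pytest.approx(rk.weights[-1], abs=1e-6)

    def test_column_permutation_equivariance(self):
        X, y = _planted_problem(seed=2, d=8)
        Xn, _, _ = minmax_normalize(X)
        perm = np.array([3, 1, 0, 7, 5, 2, 6, 4])
        rk = nca_rank(Xn, y)
        rk_p = nca_rank(Xn[:, perm], y)
        assert np.allclose(rk_p.weights, rk.weights[perm], atol=1e-9)

    def test_ranks_planted_informative_pair_top2(self):
        """The two informative features rank in the top 2 in >= 18/20 runs."""
        hits = 0
        for seed in range(20):
            X, y = _planted_problem(seed=100 + seed)
            Xn, _, _ = minmax_normalize(X)
            rk = nca_rank(Xn, y)
            hits += set(rk.order[:2].tolist()) == {0, 1}
        assert hits >= 18

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            nca_rank(np.random.default_rng(0).uniform(size=(10, 3)), np.zeros(10))

    def test_order_is_permutation_sorted_by_weight(self):
        X, y = _planted_problem(seed=3, d=10)
        Xn, _, _ = minmax_normalize(X)
        rk = nca_rank(Xn, y)
        assert sorted(rk.order.tolist()) == list(range(10))
        w = rk.weights[rk.order]
        assert np.all(np.diff(w) <= 1e-12)  # non-increasing


class TestCandidateLengths:
    def test_full_scale_range_has_901_candidates(self):
        lengths = candidate_lengths(100, 1000, n_features=22000)
        assert len(lengths) == 901
        assert lengths[0] == 100 and lengths[-1] == 1000

    def test_range_clipped_to_feature_count(self):
        lengths = candidate_lengths(100, 1000, n_features=120)
        assert lengths[0] == 100 and lengths[-1] == 120

    def test_empty_range_rejected(self):
        with pytest.raises(ValidationError):
            candidate_lengths(10, 5, n_features=20)
        with pytest.raises(ValidationError):
            candidate_lengths(0, 5, n_features=20)


class TestIncaSelect:
    def _setup(self, seed=4):
        X, y = _planted_problem(seed=seed)
        Xn, _, _ = minmax_normalize(X)
        rk = nca_rank(Xn, y)
        return Xn, y, rk

    def test_best_length_matches_brute_force_oracle(self):
        """The loop's winner equals independently evaluating all candidates."""
        Xn, y, rk = self._setup()
        cv = CVSpec(n_folds=10, seed=3)
        res = inca_select(Xn, y, rk, lo=2, hi=10, cv=cv)
        folds = make_folds(y, cv)
        oracle = []
        for l in range(2, 11):
            cm, _ = cross_validate(Xn[:, rk.order[:l]], y, cv, folds=folds)
            oracle.append(1.0 - cm.accuracy)
        assert np.allclose(res.losses, oracle)
        best = 2 + int(np.argmin(oracle))
        assert res.best_length == best

    def test_selected_is_prefix_of_ranking(self):
        Xn, y, rk = self._setup(seed=5)
        res = inca_select(Xn, y, rk, lo=3, hi=8, cv=CVSpec(seed=1))
        assert np.array_equal(res.selected, rk.order[: res.best_length])

    def test_reported_loss_self_consistent(self):
        Xn, y, rk = self._setup(seed=6)
        cv = CVSpec(seed=2)
        res = inca_select(Xn, y, rk, lo=2, hi=9, cv=cv)
        cm, _ = cross_validate(Xn[:, res.selected], y, cv, folds=make_folds(y, cv))
        assert res.best_loss == pytest.approx(1.0 - cm.accuracy)

    def test_tie_breaks_to_smallest_length(self):
        # a perfectly separable problem: loss 0 at every length -> pick lo
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        X = np.where(y[:, None] == 0, 0.0, 1.0) + rng.normal(0, 0.01, (60, 6))
        Xn, _, _ = minmax_normalize(X)
        rk = nca_rank(Xn, y)
        res = inca_select(Xn, y, rk, lo=2, hi=6, cv=CVSpec(n_folds=5, seed=0))
        assert np.all(res.losses == res.losses[0])
        assert res.best_length == 2

    def test_selection_does_not_hurt_accuracy(self):
        """Selected-subset accuracy beats or ties all features >= 80% of runs."""
        wins = 0
        for seed in range(20):
            X, y = _planted_problem(seed=200 + seed)
            Xn, _, _ = minmax_normalize(X)
            rk = nca_rank(Xn, y)
            cv = CVSpec(seed=seed)
            folds = make_folds(y, cv)
            res = inca_select(Xn, y, rk, lo=1, hi=10, cv=cv)
            cm_all, _ = cross_validate(Xn, y, cv, folds=folds)
            wins += (1.0 - res.best_loss) >= cm_all.accuracy
        assert wins >= 16


def test_no_leakage_mode_matches_faithful_on_easy_problem():
    """Fold-honest refitting still finds the informative prefix and its
    loss curve stays close to the faithful mode on a separable problem."""
    X, y = _planted_problem(seed=9, n=100, d=8)
    cv = CVSpec(n_folds=5, seed=4)
    res = inca_select_no_leakage(X, y, lo=2, hi=6, cv=cv)
    assert res.mode == "no_leakage"
    assert res.best_loss <= 0.05
    assert len(res.selected) == res.best_length
    # honest per-length losses come from pooled fold errors
    assert np.all((0 <= res.losses) & (res.losses <= 1))


def test_no_leakage_predictions_use_train_fitted_scaler():
    """A shifted test fold must be scaled by train statistics, not its own."""
    X, y = _planted_problem(seed=10, n=60, d=4)
    cv = CVSpec(n_folds=3, seed=0)
    folds = make_folds(y, cv)
    test_idx = folds[0]
    train_mask = np.ones(len(y), bool)
    train_mask[test_idx] = False
    Xtr, mins, maxs = minmax_normalize(X[train_mask])
    from shutterblinds.selection import apply_minmax

    Xte = apply_minmax(X[test_idx], mins, maxs)
    # rows outside the train range legitimately fall outside [0, 1]
    shifted = apply_minmax(X[test_idx] + 10.0, mins, maxs)
    assert shifted.min() > 1.0
    pred = knn_predict(Xtr, y[train_mask], Xte)
    assert np.mean(pred == y[test_idx]) > 0.8
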