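"""Splitting, folding, early stopping, cross-validated ensemble training."""

import numpy as np
import pytest

from aprnet.encoding import encode_dataset
from aprnet.model import ModelConfig
from aprnet.synthetic import SyntheticSpec, gen_hexapeptides
from aprnet.training import (
    hyperparameter_search,
    make_folds,
    select_stopping_epoch,
    stratified_split,
    train_crossval,
)

FAST_CONFIG = ModelConfig(
    n_bidirectional_layers=1, n_dense_layers=2, dropout=0.0,
    neurons_per_layer=(16, 16, 16), batch_size=32, learning_rate=1e-2,
)


def _labels(n_pos, n_neg, seed=0):
    y = np.array([1] * n_pos + [0] * n_neg)
    return np.random.default_rng(seed).permutation(y)


class TestStratifiedSplit:
    def test_exact_per_class_counts(self):
        y = _labels(30, 70)
        split = stratified_split(y, fraction=0.9, seed=0)
        assert np.sum(y[split.train_indices] == 1) == 27
        assert np.sum(y[split.train_indices] == 0) == 63
        assert split.test_indices.size == 10

    def test_waltzdb_sized_split_round_half_even(self):
        # 515 amyloid / 901 non-amyloid at 0.9: round-half-even puts
        # round(463.5)=464 positives and round(810.9)=811 negatives in train
        y = _labels(515, 901)
        split = stratified_split(y, fraction=0.9, seed=3)
        assert np.sum(y[split.train_indices] == 1) == 464
        assert np.sum(y[split.train_indices] == 0) == 811
        assert np.sum(y[split.test_indices] == 1) == 51
        assert np.sum(y[split.test_indices] == 0) == 90

    def test_partition_and_determinism(self):
        y = _labels(40, 60)
        a = stratified_split(y, fraction=0.8, seed=5)
        b = stratified_split(y, fraction=0.8, seed=5)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)
        np.testing.assert_array_equal(a.test_indices, b.test_indices)
        merged = np.sort(np.concatenate([a.train_indices, a.test_indices]))
        np.testing.assert_array_equal(merged, np.arange(y.size))

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_out_of_range(self, frac):
        with pytest.raises(ValueError, match="fraction"):
            stratified_split(_labels(10, 10), fraction=frac)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            stratified_split(np.ones(10, dtype=int))


class TestMakeFolds:
    def test_balanced_input_exact_division(self):
        y = _labels(25, 25)
        plan = make_folds(y, k=5, seed=1)
        for fold in range(5):
            val = np.flatnonzero(plan.fold_assignments == fold)
            assert np.sum(y[val] == 1) == 5
            assert np.sum(y[val] == 0) == 5

    def test_unbalanced_within_one(self):
        y = _labels(23, 41)
        plan = make_folds(y, k=5, seed=2)
        for cls in (0, 1):
            sizes = [np.sum((plan.fold_assignments == f) & (y == cls))
                     for f in range(5)]
            assert max(sizes) - min(sizes) <= 1

    def test_assignments_partition_indices(self):
        y = _labels(12, 18)
        plan = make_folds(y, k=5, seed=3)
        assert set(plan.fold_assignments) == set(range(5))
        total = sum((plan.fold_assignments == f).sum() for f in range(5))
        assert total == y.size

    def test_k_exceeding_minority_rejected(self):
        with pytest.raises(ValueError, match="minority"):
            make_folds(_labels(3, 50), k=5)

    def test_determinism(self):
        y = _labels(20, 20)
        np.testing.assert_array_equal(
            make_folds(y, k=5, seed=7).fold_assignments,
            make_folds(y, k=5, seed=7).fold_assignments,
        )


class TestStoppingRule:
    def test_strictly_increasing_returns_last(self):
        assert select_stopping_epoch([0.5, 0.6, 0.7, 0.8], patience=2, min_delta=0) == 4

    def test_divergence_example(self):
        assert select_stopping_epoch([0.6, 0.7, 0.7, 0.69, 0.68],
                                     patience=2, min_delta=0) == 2

    def test_constant_history_returns_first(self):
        assert select_stopping_epoch([0.7, 0.7, 0.7, 0.7], patience=2, min_delta=0) == 1

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_stopping_epoch([])

    def test_never_returns_dominated_epoch(self, rng):
        # the returned epoch is always a global argmax of the scanned prefix
        for _ in range(50):
            hist = rng.random(20)
            epoch = select_stopping_epoch(hist, patience=3, min_delta=1e-3)
            assert hist[epoch - 1] == hist[:max(epoch, 1)].max()


@pytest.fixture(scope="module")
def encoded(feature_table):
    data = gen_hexapeptides(SyntheticSpec(n_hexapeptides=150, positive_fraction=0.4,
                                          noise=0.0, seed=5))
    return encode_dataset(data, feature_table)


@pytest.fixture(scope="module")
def tiny(feature_table):
    data = gen_hexapeptides(SyntheticSpec(n_hexapeptides=60, positive_fraction=0.5,
                                          noise=0.0, seed=8))
    return encode_dataset(data, feature_table)


class TestCrossvalTraining:
    def test_ensemble_has_five_members_and_learns(self, encoded):
        X, y = encoded
        folds = make_folds(y, k=5, seed=5)
        ens = train_crossval(X, y, FAST_CONFIG, folds, seed=5, max_epochs=10)
        assert len(ens.members) == 5
        assert ens.threshold is not None
        for m in ens.members:
            best_val = m.training_history["val_auroc"][m.stopping_epoch - 1]
            assert best_val > 0.8

    def test_training_is_deterministic(self, encoded):
        X, y = encoded
        folds = make_folds(y, k=5, seed=6)
        a = train_crossval(X, y, FAST_CONFIG, folds, seed=6, max_epochs=5)
        b = train_crossval(X, y, FAST_CONFIG, folds, seed=6, max_epochs=5)
        assert [m.stopping_epoch for m in a.members] == \
               [m.stopping_epoch for m in b.members]
        np.testing.assert_array_equal(a.predict_batch(X[:8]), b.predict_batch(X[:8]))


class TestHyperparameterSearch:
    def test_budget_and_ordering(self, tiny):
        X, y = tiny
        ranked = hyperparameter_search(X, y, budget=3, strategy="random", seed=1,
                                       k=3, max_epochs=3)
        assert len(ranked) == 3
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_good_config_outranks_degenerate(self, tiny):
        X, y = tiny
        degenerate = ModelConfig(
            n_bidirectional_layers=1, n_dense_layers=1, dropout=0.8,
            neurons_per_layer=(8, 8), batch_size=16, learning_rate=1e-4,
        )
        ranked = hyperparameter_search(
            X, y, budget=2, seed=2, k=3, max_epochs=8,
            candidates=[FAST_CONFIG, degenerate],
        )
        assert ranked[0][0] == FAST_CONFIG

    def test_invalid_budget(self, tiny):
        X, y = tiny
        with pytest.raises(ValueError, match="budget"):
            hyperparameter_search(X, y, budget=0)

    def test_empty_candidate_space(self, tiny):
        X, y = tiny
        with pytest.raises(ValueError, match="empty"):
            hyperparameter_search(X, y, budget=2, candidates=[])
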