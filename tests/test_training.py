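"""Class weights, weighted loss, fold assignment, LR schedule, CV protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgbeats.model import ModelSpec
from ecgbeats.synthetic import NoiseSpec, SyntheticConfig, synth_dataset
from ecgbeats.training import (
    ReduceLROnPlateau,
    TrainConfig,
    class_weights,
    kfold_split,
    one_hot,
    run_cross_validation,
    train_final,
    weighted_cross_entropy,
)

TINY_SPEC = ModelSpec(conv_filters=(4, 4, 8), lstm_units=4, dense_units=8)


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        assert np.allclose(class_weights([10, 10, 10, 10, 10]), 1.0)

    def test_direct_formula(self):
        w = class_weights([80, 10, 5, 4, 1])
        assert np.allclose(w, [0.25, 2.0, 4.0, 5.0, 20.0])

    def test_published_training_counts(self):
        # n=87,554 with N=72,471 and F=641 beats
        counts = [72_471, 2_223, 5_788, 641, 6_431]
        w = class_weights(counts)
        assert w[0] == pytest.approx(87_554 / (5 * 72_471))
        assert w[3] == pytest.approx(87_554 / (5 * 641))
        assert w[3] / w[0] == pytest.approx(72_471 / 641)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="zero-count"):
            class_weights([5, 0, 3, 2, 1])

    @given(st.lists(st.integers(1, 10_000), min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_weight_conservation(self, counts):
        counts = np.asarray(counts)
        w = class_weights(counts)
        assert float(w @ counts) == pytest.approx(counts.sum(), rel=1e-12)
        # larger count => smaller weight
        order = np.argsort(counts)
        assert np.all(np.diff(w[order]) <= 1e-12)


class TestWeightedCrossEntropy:
    def test_perfect_predictions_zero_loss(self):
        onehot = np.eye(5)[[0, 3]]
        assert weighted_cross_entropy(onehot, onehot,
                                      np.array([1, 2, 3, 4, 5.0])) == 0.0

    def test_uniform_probs_unit_weights(self):
        probs = np.full((4, 5), 0.2)
        onehot = np.eye(5)[[0, 1, 2, 3]]
        assert weighted_cross_entropy(probs, onehot) == pytest.approx(np.log(5))

    def test_single_weighted_sample(self):
        probs = np.full((1, 5), 0.2)
        onehot = np.eye(5)[[3]]
        w = np.ones(5)
        w[3] = 27.32
        assert weighted_cross_entropy(probs, onehot, w) == pytest.approx(
            27.32 * np.log(5))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_unit_weights_equal_unweighted(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(5), size=16)
        onehot = np.eye(5)[rng.integers(0, 5, 16)]
        assert weighted_cross_entropy(probs, onehot, np.ones(5)) == \
            pytest.approx(weighted_cross_entropy(probs, onehot), abs=1e-12)


class TestKFoldSplit:
    def test_partition_properties(self, rng):
        labels = rng.integers(0, 5, 100)
        assignment = kfold_split(labels, k=10, seed=0)
        sizes = np.bincount(assignment, minlength=10)
        assert sizes.sum() == 100
        assert sizes.max() - sizes.min() <= 1

    def test_stratification_bound(self, rng):
        labels = np.repeat(np.arange(5), [500, 100, 60, 20, 20])
        assignment = kfold_split(labels, k=10, seed=3)
        global_counts = np.bincount(labels, minlength=5)
        for fold in range(10):
            fold_counts = np.bincount(labels[assignment == fold], minlength=5)
            assert np.all(np.abs(fold_counts - global_counts / 10) <= 1)

    def test_rare_class_warns_but_splits(self, caplog):
        labels = np.array([0] * 50 + [1] * 3)
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assignment = kfold_split(labels, k=5, seed=0)
        assert assignment.size == 53

    def test_seeded_determinism(self, rng):
        labels = rng.integers(0, 5, 80)
        assert np.array_equal(kfold_split(labels, k=4, seed=9),
                              kfold_split(labels, k=4, seed=9))


class TestReduceLROnPlateau:
    def test_decreasing_loss_keeps_lr(self):
        sched = ReduceLROnPlateau(0.001)
        for loss in [1.0, 0.9, 0.8, 0.7, 0.6, 0.5]:
            assert sched.update(loss) == 0.001

    def test_five_flat_epochs_halve_once(self):
        sched = ReduceLROnPlateau(0.001)
        sched.update(1.0)
        lrs = [sched.update(1.0) for _ in range(5)]
        assert lrs == [0.001] * 4 + [0.0005]

    def test_ten_flat_epochs_halve_twice(self):
        sched = ReduceLROnPlateau(0.001)
        sched.update(1.0)
        for _ in range(10):
            lr = sched.update(1.0)
        assert lr == pytest.approx(0.00025)

    @given(st.lists(st.floats(0.01, 10.0, allow_nan=False), min_size=1,
                    max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_literal_replay(self, losses):
        sched = ReduceLROnPlateau(0.001)
        got = [sched.update(l) for l in losses]
        # brute-force replay of the stated rule
        lr, best, wait, expected = 0.001, np.inf, 0, []
        for l in losses:
            if l < best:
                best, wait = l, 0
            else:
                wait += 1
                if wait >= 5:
                    lr, wait = lr * 0.5, 0
            expected.append(lr)
        assert got == expected


@pytest.fixture(scope="module")
def tiny_dataset():
    cfg = SyntheticConfig(n_beats=260,
                          class_proportions=(0.4, 0.25, 0.15, 0.1, 0.1),
                          noise=NoiseSpec.none(), seed=21)
    ds = synth_dataset(cfg)
    assert np.all(ds.class_counts >= 2)
    return ds


class TestCrossValidation:
    def test_bookkeeping(self, tiny_dataset):
        cfg = TrainConfig(epochs=2, k=2, seed=0, batch_size=64)
        cv = run_cross_validation(tiny_dataset, TINY_SPEC, cfg)
        assert cv.k == 2
        for fold in cv.folds:
            assert len(fold.history) <= 2
            assert 1 <= fold.best_epoch <= 2
        assert 1 <= cv.selected_epoch <= 2
        # validation folds partition the dataset
        all_idx = np.sort(np.concatenate([f.val_indices for f in cv.folds]))
        assert np.array_equal(all_idx, np.arange(len(tiny_dataset)))

    def test_seeded_determinism(self, tiny_dataset):
        cfg = TrainConfig(epochs=2, k=2, seed=5, batch_size=64)
        a = run_cross_validation(tiny_dataset, TINY_SPEC, cfg)
        b = run_cross_validation(tiny_dataset, TINY_SPEC, cfg)
        assert a.selected_epoch == b.selected_epoch
        assert np.array_equal(a.folds[0].val_probs, b.folds[0].val_probs)

    def test_weights_are_identity_on_balanced_data(self):
        cfg = SyntheticConfig(n_beats=100,
                              class_proportions=(0.2,) * 5,
                              noise=NoiseSpec.none(), seed=33)
        ds = synth_dataset(cfg)
        counts = ds.class_counts
        # exact multinomial balance is not guaranteed; equalize by trimming
        m = counts.min() - (counts.min() % 2)  # even, so folds stay balanced
        keep = np.concatenate([np.flatnonzero(ds.labels == c)[:m]
                               for c in range(5)])
        ds = ds.subset(np.sort(keep))
        tc = dict(epochs=1, k=2, seed=2, batch_size=64)
        cv_w = run_cross_validation(ds, TINY_SPEC,
                                    TrainConfig(use_weights=True, **tc))
        cv_u = run_cross_validation(ds, TINY_SPEC,
                                    TrainConfig(use_weights=False, **tc))
        for fw, fu in zip(cv_w.folds, cv_u.folds):
            assert fw.history[-1].loss == pytest.approx(fu.history[-1].loss,
                                                        rel=1e-9)


class TestTrainFinal:
    def test_single_epoch_returns(self, tiny_dataset):
        cfg = TrainConfig(epochs=5, k=2, seed=0, batch_size=64)
        handle = train_final(tiny_dataset, TINY_SPEC, cfg, optimal_epoch=1)
        assert handle.n_params == handle.table.total

    def test_invalid_epoch_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            train_final(tiny_dataset, TINY_SPEC,
                        TrainConfig(k=2), optimal_epoch=0)

    def test_learns_separable_classes(self, tiny_dataset):
        from ecgbeats.model import predict
        spec = ModelSpec(conv_filters=(8, 16, 32), lstm_units=16,
                         dense_units=64)
        cfg = TrainConfig(epochs=40, k=2, seed=1, batch_size=64,
                          initial_lr=0.003)
        handle = train_final(tiny_dataset, spec, cfg, optimal_epoch=40)
        probs = predict(handle, tiny_dataset.segments)
        acc = (probs.argmax(1) == tiny_dataset.labels).mean()
        assert acc >= 0.95


class TestTrainConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"lr_factor": 1.5}, {"k": 1}, {"lr_patience": 0},
        {"optimizer": "sgd"},
    ])
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)
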