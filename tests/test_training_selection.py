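import numpy as np
import pytest

from n1loc.dataset_pipeline import interleaved_split
from n1loc.encoding import encode_dataset
from n1loc.n1nn_core import N1NNConfig
from n1loc.synthetic_fixtures import GeneratorSpec, generate_dataset
from n1loc.training_selection import (Checkpoint, TrainConfig,
                                      TrainingDivergedError, grid_search,
                                      select_best, sgd_train)


def encode_labeled(records):
    return [(pm.values, r.label) for pm, r in zip(encode_dataset(records), records)]


def toy_sets(n_classes=2, n_per_class=5, seed=4):
    spec = GeneratorSpec(n_classes=n_classes, n_per_class=n_per_class, seed=seed)
    records = generate_dataset(spec)
    split = interleaved_split(records)
    return encode_labeled(split.train), encode_labeled(split.validation)


TINY = N1NNConfig(c=1, gamma=0, n_hidden_kernels=0, input_width=22,
                  kernel_hidden_units=4, state_units=4, fc_hidden_units=4)


class TestTrainConfig:
    def test_checkpoint_interval_must_divide_total_epochs(self):
        with pytest.raises(ValueError, match="divide"):
            TrainConfig(total_epochs=25, checkpoint_every=10)

    def test_checkpoint_count_property(self):
        assert TrainConfig(total_epochs=5000, checkpoint_every=10).n_checkpoints == 500


class TestSgdTrain:
    def test_checkpoint_count_equals_epochs_over_interval(self):
        train, valid = toy_sets()
        cps = sgd_train(TINY, TrainConfig(total_epochs=20, checkpoint_every=10,
                                          seed=1), train, valid)
        assert len(cps) == 2
        assert [c.epoch for c in cps] == [10, 20]

    def test_same_seed_reproduces_bitwise_identical_runs(self):
        train, valid = toy_sets()
        t = TrainConfig(total_epochs=30, checkpoint_every=10, seed=9)
        cps1 = sgd_train(TINY, t, train, valid)
        cps2 = sgd_train(TINY, t, train, valid)
        assert [c.validation_accuracy for c in cps1] == \
               [c.validation_accuracy for c in cps2]
        for a, b in zip(cps1[-1].params.arrays(), cps2[-1].params.arrays()):
            np.testing.assert_array_equal(a, b)

    def test_empty_sets_rejected(self):
        train, valid = toy_sets()
        with pytest.raises(ValueError):
            sgd_train(TINY, TrainConfig(total_epochs=10, checkpoint_every=10,
                                        seed=1), [], valid)

    def test_divergence_reports_epoch_and_example(self):
        train, valid = toy_sets()
        # absurd learning rate with weight decay explodes the weights
        t = TrainConfig(total_epochs=10, checkpoint_every=10, seed=1,
                        learning_rate=1e6, weight_decay=1e6)
        with pytest.raises(TrainingDivergedError, match="epoch"):
            sgd_train(TINY, t, train, valid)

    def test_two_class_motif_data_is_learned_within_200_epochs(self):
        """Separable two-class motif data: a small net reaches >= 0.9 validation."""
        train, valid = toy_sets(n_classes=2, n_per_class=30, seed=15)
        cfg = N1NNConfig(c=3, gamma=0, n_hidden_kernels=0, input_width=22,
                         kernel_hidden_units=12, state_units=12, fc_hidden_units=12)
        t = TrainConfig(learning_rate=0.1, momentum=0.9, total_epochs=200,
                        checkpoint_every=10, seed=3)
        cps = sgd_train(cfg, t, train, valid)
        assert max(c.validation_accuracy for c in cps) >= 0.9

    def test_training_loss_trends_downward_on_separable_data(self):
        train, valid = toy_sets(n_classes=2, n_per_class=30, seed=15)
        cfg = N1NNConfig(c=3, gamma=0, n_hidden_kernels=0, input_width=22,
                         kernel_hidden_units=12, state_units=12, fc_hidden_units=12)
        t = TrainConfig(learning_rate=0.1, momentum=0.9, total_epochs=200,
                        checkpoint_every=10, seed=3)
        losses = [c.train_loss for c in sgd_train(cfg, t, train, valid)]
        smooth = np.convolve(losses, np.ones(5) / 5, mode="valid")
        assert smooth[-1] < smooth[0]
        assert (np.diff(smooth) < 1e-3).mean() > 0.8  # non-increasing in trend


class TestSelectBest:
    def _fake(self, epoch, acc):
        return Checkpoint(epoch=epoch, params=None, config=TINY,
                          validation_accuracy=acc, train_loss=0.0)

    def test_matches_brute_force_sort_and_slice(self, rng):
        cps = [self._fake((i + 1) * 10, float(rng.random()))
               for i in range(50)]
        got = select_best(cps, 6)
        expected = sorted(cps, key=lambda c: (-c.validation_accuracy, c.epoch))[:6]
        assert got == expected

    def test_all_equal_accuracies_pick_earliest_epochs(self):
        cps = [self._fake((i + 1) * 10, 0.5) for i in range(10)]
        assert [c.epoch for c in select_best(cps, 3)] == [10, 20, 30]

    def test_requesting_more_than_available_fails(self):
        cps = [self._fake(10, 0.5)]
        with pytest.raises(ValueError):
            select_best(cps, 2)


class TestGridSearch:
    def test_single_cell_grid_yields_one_row(self):
        train, valid = toy_sets()
        t = TrainConfig(total_epochs=10, checkpoint_every=10, seed=1)
        rows = grid_search([(TINY, t)], train, valid)
        assert len(rows) == 1
        assert rows[0].best_accuracy is not None

    def test_cell_failures_are_recorded_and_grid_continues(self):
        train, valid = toy_sets()
        ok = TrainConfig(total_epochs=10, checkpoint_every=10, seed=1)
        bad = TrainConfig(total_epochs=10, checkpoint_every=10, seed=1,
                          learning_rate=1e6, weight_decay=1e6)
        rows = grid_search([(TINY, bad), (TINY, ok)], train, valid)
        assert len(rows) == 2
        assert rows[0].error is not None and rows[0].best_accuracy is None
        assert rows[1].error is None

    def test_context_gamma1_never_trails_gamma0_on_order_only_motifs(self):
        """Two classes share residue composition exactly (span-3 motifs WWC vs
        CWW), so a gamma=0 network reading single columns is capped at chance
        while gamma=1 can in principle read the adjacency."""
        spec = GeneratorSpec(n_classes=2, n_per_class=20, seed=5,
                             motifs=("WWC", "CWW") + GeneratorSpec().motifs[2:])
        records = generate_dataset(spec)
        split = interleaved_split(records)
        train, valid = encode_labeled(split.train), encode_labeled(split.validation)
        grid = []
        for gamma in (0, 1):
            cfg = N1NNConfig(c=0, gamma=gamma, n_hidden_kernels=1, input_width=22,
                             kernel_hidden_units=8, state_units=8, fc_hidden_units=8)
            grid.append((cfg, TrainConfig(learning_rate=0.1, momentum=0.9,
                                          total_epochs=50, checkpoint_every=10,
                                          seed=21)))
        rows = grid_search(grid, train, valid)
        acc0, acc1 = rows[0].best_accuracy, rows[1].best_accuracy
        assert acc1 >= acc0
        assert acc0 <= 0.75  # composition-blindness keeps gamma=0 near chance
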