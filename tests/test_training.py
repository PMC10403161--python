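"""Training protocol: split, batches, schedule, optimization loop."""
import numpy as np
import pytest

import mgaca.training as training
from mgaca.masks import DatasetManifest
from mgaca.model import build_mgaca
from mgaca.nn import autodiff as ad
from mgaca.training import (PlateauScheduler, TrainConfig, TrainingDiverged,
                            batch_generator, bce_dice_loss_var,
                            lr_schedule_step, split_dataset, train)

SMALL_NET = dict(width_multiplier=0.125, input_shape=(16, 16, 3))


class TestSplit:
    @pytest.mark.parametrize("n", [4, 10, 37, 100, 1001])
    def test_disjoint_cover_and_validation_size(self, n):
        split = split_dataset(n)
        assert len(set(split.train) & set(split.validation)) == 0
        assert sorted(np.concatenate([split.train, split.validation])) == \
            list(range(n))
        assert len(split.validation) == int(np.ceil(0.25 * n))

    def test_deterministic_under_seed(self):
        a, b = split_dataset(50), split_dataset(50)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.validation, b.validation)

    def test_tiny_and_invalid_sizes(self):
        split = split_dataset(4)
        assert (len(split.train), len(split.validation)) == (3, 1)
        with pytest.raises(ValueError):
            split_dataset(1)


class TestLRSchedule:
    def test_forced_plateaus_walk_down_to_floor(self):
        sched = PlateauScheduler(0.001, factor=0.2, patience=2, min_lr=1e-5)
        seen = []
        sched.step(1.0)  # initial best
        for _ in range(12):
            seen.append(sched.step(1.0))  # never improves
        distinct = sorted(set(seen), reverse=True)
        assert distinct == pytest.approx([1e-3, 2e-4, 4e-5, 1e-5])
        assert seen[-1] == pytest.approx(1e-5)  # clamped at the floor

    def test_improving_stream_keeps_lr(self):
        sched = PlateauScheduler(0.001)
        for loss in [1.0, 0.9, 0.8, 0.7, 0.6]:
            assert sched.step(loss) == 0.001

    def test_stateless_rule_matches_contract(self):
        cfg = TrainConfig()
        assert lr_schedule_step([1.0, 0.9, 0.8, 0.7], 1e-3, cfg) == 1e-3
        assert lr_schedule_step([0.5, 0.9, 0.9, 0.9], 1e-3, cfg) == \
            pytest.approx(2e-4)
        assert lr_schedule_step([0.5, 0.9, 0.9, 0.9], 1.2e-5, cfg) == 1e-5


class TestBatchGenerator:
    def test_batch_arithmetic_and_binarity(self, tiny_dataset):
        out, manifest = tiny_dataset
        cfg = TrainConfig(batch_size=10, target_size=(32, 32))
        n = len(manifest)
        batches = list(batch_generator(manifest, np.arange(n), cfg,
                                       shuffle=False))
        sizes = [len(x) for x, _ in batches]
        assert sum(sizes) == n
        assert all(s == 10 for s in sizes[:-1]) and sizes[-1] == n % 10 or \
            sizes[-1] == 10
        for x, y in batches:
            assert x.shape[1:] == (32, 32, 3) and y.shape[1:] == (32, 32, 1)
            assert x.min() >= 0.0 and x.max() <= 1.0
            assert set(np.unique(y)) <= {0.0, 1.0}

    def test_same_rng_reproduces_batch_sequence(self, tiny_dataset):
        out, manifest = tiny_dataset
        cfg = TrainConfig(batch_size=5, target_size=(32, 32))
        idx = np.arange(len(manifest))
        run1 = [x for x, _ in batch_generator(
            manifest, idx, cfg, rng=np.random.default_rng(3), shuffle=True)]
        run2 = [x for x, _ in batch_generator(
            manifest, idx, cfg, rng=np.random.default_rng(3), shuffle=True)]
        for a, b in zip(run1, run2):
            np.testing.assert_array_equal(a, b)


def toy_arrays(n=6, size=16, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, size, size, 3)).astype(np.float32) * 0.3
    Y = np.zeros((n, size, size, 1), dtype=np.float32)
    Y[:, 4:12, 4:12] = 1.0
    X[:, 4:12, 4:12] += 0.4
    return np.clip(X, 0, 1), Y


class TestTrainLoop:
    def test_single_step_decreases_loss_in_seeded_trials(self):
        """One Adam step from random init lowers BCE+Dice in >=95% of trials."""
        X, Y = toy_arrays()
        wins = 0
        n_trials = 20
        for seed in range(n_trials):
            net = build_mgaca(seed=seed, **SMALL_NET)
            before = float(bce_dice_loss_var(
                ad.constant(Y), net.forward(X, training=True)).data)
            train(net, (X, Y), TrainConfig(batch_size=6, max_epochs=1,
                                           global_seed=seed), n_steps=1)
            after = float(bce_dice_loss_var(
                ad.constant(Y), net.forward(X, training=True)).data)
            wins += after < before
        assert wins >= 0.95 * n_trials

    def test_history_lr_never_increases_and_best_before_stop(self):
        X, Y = toy_arrays()
        cfg = TrainConfig(batch_size=6, max_epochs=6, global_seed=1)
        net = build_mgaca(seed=1, **SMALL_NET)
        history = train(net, (X, Y), cfg)
        lrs = history.column("lr")
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert all(lr >= cfg.min_lr for lr in lrs)
        assert 0 <= history.best_epoch <= history.stopped_epoch

    def test_early_stop_triggers_at_best_plus_patience(self, monkeypatch):
        X, Y = toy_arrays(n=2)
        losses = iter([1.0] + [1.0 + 0.1 * k for k in range(1, 30)])
        monkeypatch.setattr(training, "_dataset_loss",
                            lambda *a, **k: next(losses))
        cfg = TrainConfig(batch_size=2, max_epochs=30, early_stop_patience=3,
                          global_seed=0)
        net = build_mgaca(seed=0, **SMALL_NET)
        history = train(net, (X, Y), cfg, val_data=(X, Y))
        assert history.best_epoch == 0
        assert history.stopped_epoch == history.best_epoch + 3

    def test_validation_items_never_reach_the_optimizer(self):
        n = 8
        X = np.stack([np.full((16, 16, 3), (i + 1) / (n + 1), dtype=np.float32)
                      for i in range(n)])
        Y = np.zeros((n, 16, 16, 1), dtype=np.float32)
        cfg = TrainConfig(split_fraction=0.25, batch_size=4, max_epochs=2,
                          global_seed=0)
        split = split_dataset(n, cfg)
        net = build_mgaca(seed=0, **SMALL_NET)
        seen_training_values = set()
        original = net.forward

        def instrumented(x, training=False):
            if training:
                seen_training_values.update(
                    np.unique(np.asarray(x if not isinstance(x, ad.Var)
                                         else x.data)).round(6).tolist())
            return original(x, training=training)

        net.forward = instrumented
        train(net, (X[split.train], Y[split.train]), cfg,
              val_data=(X[split.validation], Y[split.validation]))
        val_values = {round((i + 1) / (n + 1), 6) for i in split.validation}
        assert not (seen_training_values & val_values)

    def test_nan_loss_aborts_with_diagnostic(self, monkeypatch):
        X, Y = toy_arrays(n=2)

        def nan_loss(truth, probs, **kw):
            return ad.constant(np.float32(np.nan))

        monkeypatch.setattr(training, "bce_dice_loss_var", nan_loss)
        net = build_mgaca(seed=0, **SMALL_NET)
        with pytest.raises(TrainingDiverged, match="lr="):
            train(net, (X, Y), TrainConfig(batch_size=2, max_epochs=1))

    def test_loss_decreases_from_first_to_best_epoch(self):
        X, Y = toy_arrays()
        net = build_mgaca(seed=3, **SMALL_NET)
        history = train(net, (X, Y),
                        TrainConfig(batch_size=6, max_epochs=8, global_seed=3))
        losses = history.column("train_loss")
        assert min(losses) < losses[0]


class TestConfigValidation:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(split_fraction=0.0)
        with pytest.raises(ValueError):
            TrainConfig(plateau_factor=1.5)
        with pytest.raises(ValueError):
            TrainConfig(min_lr=0.1, initial_lr=0.01)
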