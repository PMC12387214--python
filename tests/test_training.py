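"""Loss, schedule callbacks and the training loop."""

import numpy as np
import pytest

from fundusnet import (
    ArchitectureSpec,
    AugmentationConfig,
    TrainingConfig,
    TrainingHistory,
    build_model,
    early_stop,
    plateau_lr,
    regularized_loss,
    stratified_split,
    train,
)


class TestRegularizedLoss:
    def test_perfect_predictions_give_zero(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert regularized_loss(probs, [0, 1, 2], [], 0.01) == 0.0

    def test_uniform_predictions_give_log_n(self):
        probs = np.full((4, 10), 0.1)
        assert regularized_loss(probs, [0, 3, 5, 9], [], 0.01) == pytest.approx(
            np.log(10.0), abs=1e-12
        )

    def test_matches_scalar_loop_oracle(self, rng):
        probs = rng.random((4, 3)) + 0.05
        probs /= probs.sum(axis=1, keepdims=True)
        y = np.array([2, 0, 1, 1])
        w1 = rng.standard_normal((3, 2))
        w2 = rng.standard_normal(4)
        lam = 0.01
        expected = 0.0
        for n in range(4):
            expected -= np.log(probs[n, y[n]])
        expected /= 4
        pen = sum(w1[i, j] ** 2 for i in range(3) for j in range(2))
        pen += sum(v**2 for v in w2)
        expected += lam * pen
        got = regularized_loss(probs, y, [w1, w2], lam)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_penalty_weighting(self, rng):
        probs = np.eye(2)[[0, 1]]
        w = np.array([2.0, -1.0])
        assert regularized_loss(probs, [0, 1], [w], 0.5) == pytest.approx(2.5)


class TestPlateauSchedule:
    def test_improving_loss_keeps_rate(self):
        h = TrainingHistory.from_val_losses([1.0, 0.9, 0.8, 0.7])
        assert plateau_lr(h, TrainingConfig()) == 1e-4

    def test_five_stagnant_epochs_halve_rate(self):
        h = TrainingHistory.from_val_losses([1.0] + [1.0] * 5)
        assert plateau_lr(h, TrainingConfig()) == pytest.approx(5e-5)

    def test_rate_floors_at_min_lr(self):
        h = TrainingHistory.from_val_losses([1.0] * 200)
        assert plateau_lr(h, TrainingConfig()) == pytest.approx(1e-6)

    def test_counter_resets_on_improvement(self):
        # 4 stagnant, improve, 4 stagnant: never 5 consecutive
        h = TrainingHistory.from_val_losses([1.0, 1.0, 1.0, 1.0, 1.0, 0.5, 0.5, 0.5, 0.5, 0.5])
        assert plateau_lr(h, TrainingConfig()) == 1e-4


class TestEarlyStop:
    def test_fifteen_stagnant_epochs_trigger_stop(self):
        h = TrainingHistory.from_val_losses([1.0, 0.8] + [0.9] * 15)
        stop, restore = early_stop(h, TrainingConfig())
        assert stop and restore == 2

    def test_monotone_improvement_never_stops(self):
        h = TrainingHistory.from_val_losses(np.linspace(2.0, 0.1, 50))
        stop, restore = early_stop(h, TrainingConfig())
        assert not stop and restore == 50

    def test_restore_epoch_is_argmin(self):
        h = TrainingHistory.from_val_losses([1.0, 0.9] + [0.95] * 15)
        stop, restore = early_stop(h, TrainingConfig())
        assert stop and restore == 2


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def tiny_problem(self):
        """A linearly separable toy image problem: class = brightest quadrant."""
        rng = np.random.default_rng(0)
        n_per, size = 12, 32
        images, labels = [], []
        for cls in range(4):
            for _ in range(n_per):
                img = rng.random((size, size, 3)) * 0.2
                ys = slice(0, 16) if cls < 2 else slice(16, 32)
                xs = slice(0, 16) if cls % 2 == 0 else slice(16, 32)
                img[ys, xs] += 0.7
                images.append(np.clip(img, 0, 1))
                labels.append(cls)
        return np.stack(images), np.asarray(labels)

    @pytest.fixture(scope="class")
    def short_run(self, tiny_problem):
        images, labels = tiny_problem
        spec = ArchitectureSpec(
            input_height=32, input_width=32, stem_filters=4,
            block_channels=(8, 8, 8, 16), se_reduction=2, dense_units=(16, 8),
            num_classes=4, dropout_rate=0.0, bn_momentum=0.8,
        )
        model = build_model(spec, seed=0)
        split = stratified_split(labels, seed=0)
        config = TrainingConfig(learning_rate=1e-3, max_epochs=6, batch_size=16,
                                seed=0, l2_lambda=0.001)
        aug = AugmentationConfig(rotation_deg=0, shift_frac=0, shear_frac=0,
                                 zoom_frac=0, horizontal_flip=False)
        return train(model, images, labels, split, config, aug)

    def test_loss_decreases_on_separable_data(self, short_run):
        _, history = short_run
        losses = [r.train_loss for r in history.records]
        assert losses[-1] < losses[0]

    def test_history_respects_epoch_budget(self, short_run):
        _, history = short_run
        assert len(history.records) <= 50
        assert history.best_epoch <= history.stopped_epoch

    def test_lr_sequence_non_increasing(self, short_run):
        _, history = short_run
        lrs = [r.lr for r in history.records]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert all(lr >= 1e-6 for lr in lrs)

    def test_identical_seeds_reproduce_history(self, tiny_problem):
        images, labels = tiny_problem
        spec = ArchitectureSpec(
            input_height=32, input_width=32, stem_filters=4,
            block_channels=(8, 8, 8, 8), se_reduction=2, dense_units=(8, 8),
            num_classes=4, dropout_rate=0.5, bn_momentum=0.8,
        )
        split = stratified_split(labels, seed=1)
        config = TrainingConfig(learning_rate=1e-3, max_epochs=2, batch_size=16, seed=5)
        runs = []
        for _ in range(2):
            model = build_model(spec, seed=9)
            _, history = train(model, images, labels, split, config)
            runs.append([(r.train_loss, r.val_loss, r.val_acc) for r in history.records])
        assert runs[0] == runs[1]
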