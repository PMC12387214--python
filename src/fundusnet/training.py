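"""Training loop: Adam, ℓ2-penalized cross-entropy, plateau schedule,
early stopping with best-weight restoration, checkpointing.

The objective is the batch-mean negative log-likelihood of the true classes
plus ``λ · Σ w²`` over the penalized weights (λ = 0.01, applied to the two
hidden dense-layer kernels by default, or to every trainable tensor with
``l2_global=True``). The learning-rate schedule halves the rate after 5
epochs without validation-loss improvement, floored at 1e-6; training stops
after 15 stagnant epochs and the best checkpoint (highest validation
accuracy) is restored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn.network import Network, stable_softmax
from .pipeline import AugmentationConfig, SplitBundle, augment_batch

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "EpochRecord",
    "TrainingHistory",
    "DivergenceError",
    "regularized_loss",
    "plateau_lr",
    "early_stop",
    "train",
]


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    max_epochs: int = 50
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    min_lr: float = 1e-6
    early_stop_patience: int = 15
    l2_lambda: float = 0.01
    l2_global: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.min_lr > self.learning_rate:
            raise ValueError("min_lr must not exceed learning_rate")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class EpochRecord:
    epoch: int  # 1-based
    lr: float
    train_loss: float
    train_acc: float
    val_loss: float
    val_acc: float


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int | None = None
    stopped_epoch: int | None = None

    @classmethod
    def from_val_losses(cls, val_losses, lr: float = 1e-4) -> "TrainingHistory":
        """Build a scripted history (for exercising the callbacks alone)."""
        recs = [
            EpochRecord(i + 1, lr, np.nan, np.nan, float(v), np.nan)
            for i, v in enumerate(val_losses)
        ]
        return cls(records=recs)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.records])


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def regularized_loss(
    probabilities: np.ndarray,
    true_labels: np.ndarray,
    penalized_weights=(),
    l2_lambda: float = 0.01,
) -> float:
    """Batch-mean negative log-probability of the true classes plus
    ``λ Σ w²`` over the penalized weight tensors."""
    probs = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(true_labels, dtype=np.int64)
    p_true = probs[np.arange(y.shape[0]), y]
    if np.any(p_true < 1e-12):
        logger.warning("true-class probability underflow; clamping at 1e-12")
        p_true = np.clip(p_true, 1e-12, None)
    nll = -np.mean(np.log(p_true))
    penalty = sum(float(np.sum(np.square(w))) for w in penalized_weights)
    return float(nll + l2_lambda * penalty)


def plateau_lr(history: TrainingHistory, config: TrainingConfig) -> float:
    """Learning rate for the epoch following ``history``.

    The rate is multiplied by ``plateau_factor`` (floored at ``min_lr``)
    each time the validation loss fails to improve for ``plateau_patience``
    consecutive epochs; the stagnation counter resets on improvement and
    after each reduction.
    """
    lr = config.learning_rate
    best = np.inf
    wait = 0
    for rec in history.records:
        if rec.val_loss < best:
            best = rec.val_loss
            wait = 0
        else:
            wait += 1
        if wait >= config.plateau_patience:
            lr = max(lr * config.plateau_factor, config.min_lr)
            wait = 0
    return lr


def early_stop(history: TrainingHistory, config: TrainingConfig) -> tuple[bool, int | None]:
    """Whether training should stop, and the epoch whose weights to restore
    (the first epoch attaining the minimum validation loss)."""
    best = np.inf
    best_epoch = None
    wait = 0
    for rec in history.records:
        if rec.val_loss < best:
            best = rec.val_loss
            best_epoch = rec.epoch
            wait = 0
        else:
            wait += 1
        if wait >= config.early_stop_patience:
            return True, best_epoch
    return False, best_epoch


class _Adam:
    def __init__(self, params, beta1, beta2, eps=1e-7):
        self.params = params  # list of (name, Param), trainable only
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {n: np.zeros_like(p.value) for n, p in params}
        self.v = {n: np.zeros_like(p.value) for n, p in params}
        self.t = 0

    def step(self, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params:
            g = p.grad
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _evaluate_pass(model, x, y, penalized, lam, batch_size):
    losses, correct = [], 0
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        yb = y[start : start + batch_size]
        probs = stable_softmax(model.forward(xb, training=False))
        losses.append(
            (regularized_loss(probs, yb, penalized, lam), xb.shape[0])
        )
        correct += int(np.sum(probs.argmax(axis=1) == yb))
    total = sum(n for _, n in losses)
    loss = sum(l * n for l, n in losses) / total
    return loss, correct / total


def train(
    model: Network,
    images: np.ndarray,
    labels: np.ndarray,
    split: SplitBundle,
    config: TrainingConfig | None = None,
    augmentation: AugmentationConfig | None = None,
) -> tuple[Network, TrainingHistory]:
    """Train ``model`` on the train split with per-epoch augmentation and
    validation, applying checkpoint → plateau → early-stop callbacks in
    order; the returned model carries the best checkpoint's weights."""
    config = config or TrainingConfig()
    augmentation = augmentation if augmentation is not None else AugmentationConfig()
    rng = np.random.default_rng(config.seed)
    x = np.asarray(images, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    x_train, y_train = x[split.train], y[split.train]
    x_val, y_val = x[split.val], y[split.val]
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("train and validation splits must be non-empty")

    trainable = [(n, p) for n, p in model.parameters() if p.trainable]
    if config.l2_global:
        penalized_names = [n for n, _ in trainable]
    else:
        penalized_names = list(getattr(model, "l2_penalized", []))
    penalized = [p for n, p in trainable if n in penalized_names]
    lam = config.l2_lambda
    optimizer = _Adam(trainable, config.beta1, config.beta2)

    history = TrainingHistory()
    lr = config.learning_rate
    best_val_acc = -np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    plateau_best, plateau_wait = np.inf, 0
    stop_best, stop_wait = np.inf, 0
    n_classes = model.spec.num_classes if hasattr(model, "spec") else int(y.max()) + 1

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(x_train.shape[0])
        batch_losses, correct = [], 0
        for start in range(0, order.shape[0], config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = augment_batch(x_train[idx], augmentation, rng)
            yb = y_train[idx]
            logits = model.forward(xb, training=True, rng=rng)
            probs = stable_softmax(logits)
            loss = regularized_loss(probs, yb, [p.value for p in penalized], lam)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check the input scaling"
                )
            batch_losses.append((loss, idx.shape[0]))
            correct += int(np.sum(probs.argmax(axis=1) == yb))
            dlogits = probs.copy()
            dlogits[np.arange(yb.shape[0]), yb] -= 1.0
            dlogits /= yb.shape[0]
            model.zero_grads()
            model.backward(dlogits)
            for p in penalized:
                p.grad += 2.0 * lam * p.value
            optimizer.step(lr)
        total = sum(n for _, n in batch_losses)
        train_loss = sum(l * n for l, n in batch_losses) / total
        train_acc = correct / total
        val_loss, val_acc = _evaluate_pass(
            model, x_val, y_val, [p.value for p in penalized], lam, config.batch_size
        )
        history.records.append(
            EpochRecord(epoch, lr, train_loss, train_acc, val_loss, val_acc)
        )
        logger.info(
            "epoch %d: lr=%.2e train_loss=%.4f train_acc=%.3f val_loss=%.4f val_acc=%.3f",
            epoch, lr, train_loss, train_acc, val_loss, val_acc,
        )
        # callbacks, in order: checkpoint -> plateau -> early stop
        if val_acc > best_val_acc:
            best_val_acc = val_acc
            best_weights = model.get_weights()
            best_epoch = epoch
        if val_loss < plateau_best:
            plateau_best, plateau_wait = val_loss, 0
        else:
            plateau_wait += 1
            if plateau_wait >= config.plateau_patience:
                lr = max(lr * config.plateau_factor, config.min_lr)
                plateau_wait = 0
        if val_loss < stop_best:
            stop_best, stop_wait = val_loss, 0
        else:
            stop_wait += 1
            if stop_wait >= config.early_stop_patience:
                history.stopped_epoch = epoch
                break
    if history.stopped_epoch is None:
        history.stopped_epoch = history.records[-1].epoch
    history.best_epoch = best_epoch if best_epoch else history.stopped_epoch
    model.set_weights(best_weights)
    return model, history
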