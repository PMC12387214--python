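"""Model/Results interface over the full screening pipeline.

``ScreeningModel`` holds the data and the configuration; ``fit`` balances,
splits, builds and trains the network and returns a ``ScreeningResults``
carrying the trained weights, the training history, held-out metrics and
saliency-map access::

    model = ScreeningModel.from_directory("fundus_images")
    results = model.fit(seed=7)
    print(results.summary())
    report, cm = results.evaluate()
    smap = results.saliency(results.test_images[0])
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import ArchitectureSpec, build_model, count_parameters, forward
from .cam import grad_cam, grad_cam_pp
from .metrics import ConfusionMatrix, MetricsReport, evaluate as _evaluate
from .pipeline import (
    AugmentationConfig,
    DatasetBundle,
    SmoteConfig,
    SplitBundle,
    load_dataset,
    smote_balance,
    stratified_split,
)
from .training import TrainingConfig, TrainingHistory, train

__all__ = ["ScreeningModel", "ScreeningResults"]


class ScreeningModel:
    """The ten-class fundus screening model, bound to a dataset.

    Parameters
    ----------
    images, labels, class_names
        The dataset: n×H×W×3 images in [0,1], integer labels, ordered names.
    arch
        Architecture specification; defaults to the full-width published
        network sized to the images.
    smote
        SMOTE settings; ``balance=False`` skips balancing entirely.
    split_first
        Split before balancing (leak-free) instead of the published
        balance-then-split order.
    """

    def __init__(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        class_names: list[str],
        arch: ArchitectureSpec | None = None,
        smote: SmoteConfig | None = None,
        augmentation: AugmentationConfig | None = None,
        split_fractions=(0.70, 0.15, 0.15),
        balance: bool = True,
        split_first: bool = False,
    ):
        self.images = np.asarray(images, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int64)
        self.class_names = list(class_names)
        size = self.images.shape[1]
        self.arch = arch or ArchitectureSpec(
            input_height=size, input_width=size, num_classes=len(self.class_names)
        )
        self.smote = smote or SmoteConfig()
        self.augmentation = augmentation
        self.split_fractions = tuple(split_fractions)
        self.balance = balance
        self.split_first = split_first

    @classmethod
    def from_directory(cls, root_dir, target_size: int = 150, **kwargs) -> "ScreeningModel":
        bundle = load_dataset(root_dir, target_size=target_size)
        return cls.from_bundle(bundle, **kwargs)

    @classmethod
    def from_bundle(cls, bundle: DatasetBundle, **kwargs) -> "ScreeningModel":
        return cls(bundle.images, bundle.labels, bundle.class_names, **kwargs)

    # ------------------------------------------------------------------
    def prepare(self, seed: int = 0) -> tuple[np.ndarray, np.ndarray, SplitBundle]:
        """Balance (unless disabled) and split; returns (images, labels,
        split) in the configured order."""
        x, y = self.images, self.labels
        n, h, w, c = x.shape
        if self.split_first or not self.balance:
            split = stratified_split(y, self.split_fractions, seed=seed)
            if self.balance:
                # balance the training portion only
                flat = x[split.train].reshape(len(split.train), -1)
                bx, by = smote_balance(flat, y[split.train], self.smote)
                extra = bx[len(split.train):].reshape(-1, h, w, c)
                x = np.concatenate([x, extra])
                y = np.concatenate([y, by[len(split.train):]])
                split = SplitBundle(
                    train=np.concatenate([split.train, np.arange(n, x.shape[0])]),
                    val=split.val,
                    test=split.test,
                    fractions=split.fractions,
                    seed=seed,
                )
            return x, y, split
        flat = x.reshape(n, -1)
        bx, by = smote_balance(flat, y, self.smote)
        bx = np.clip(bx, 0.0, 1.0).reshape(-1, h, w, c)
        split = stratified_split(by, self.split_fractions, seed=seed)
        return bx, by, split

    def fit(
        self,
        training: TrainingConfig | None = None,
        seed: int | None = None,
        model_seed: int | None = None,
    ) -> "ScreeningResults":
        training = training or TrainingConfig()
        seed = training.seed if seed is None else seed
        if seed != training.seed:
            training = TrainingConfig(**{**vars(training), "seed": seed})
        x, y, split = self.prepare(seed=seed)
        net = build_model(self.arch, seed=seed if model_seed is None else model_seed)
        net, history = train(
            net, x, y, split, config=training, augmentation=self.augmentation
        )
        return ScreeningResults(
            network=net,
            history=history,
            images=x,
            labels=y,
            split=split,
            class_names=self.class_names,
        )


@dataclass
class ScreeningResults:
    """Trained network plus everything needed to judge and explain it."""

    network: object
    history: TrainingHistory
    images: np.ndarray
    labels: np.ndarray
    split: SplitBundle
    class_names: list[str] = field(default_factory=list)

    @property
    def test_images(self) -> np.ndarray:
        return self.images[self.split.test]

    @property
    def test_labels(self) -> np.ndarray:
        return self.labels[self.split.test]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        return forward(self.network, images)

    def evaluate(self, indices=None) -> tuple[MetricsReport, ConfusionMatrix]:
        idx = self.split.test if indices is None else indices
        return _evaluate(
            self.network, self.images, self.labels, idx, class_names=self.class_names
        )

    def saliency(self, image: np.ndarray, class_index: int | None = None,
                 method: str = "gradcam", layer: str | None = None):
        if class_index is None:
            class_index = int(self.predict_proba(image)[0].argmax())
        fn = {"gradcam": grad_cam, "gradcampp": grad_cam_pp}[method]
        return fn(self.network, image, class_index, layer)

    def summary(self) -> str:
        ps = count_parameters(self.network)
        report, _ = self.evaluate()
        last = self.history.records[-1]
        lines = [
            "Fundus screening model",
            "=" * 58,
            ps.to_text(),
            "",
            f"Epochs run: {last.epoch} (best epoch {self.history.best_epoch})",
            f"Final val accuracy: {last.val_acc:.3f}  val loss: {last.val_loss:.3f}",
            "",
            "Held-out test metrics",
            "-" * 58,
            report.to_text(),
        ]
        return "\n".join(lines)
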