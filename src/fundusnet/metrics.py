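"""Confusion matrices and per-class / macro classification metrics.

Per class c (one-vs-rest): TP = cm[c][c], FP = column sum − TP,
FN = row sum − TP; precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
harmonic mean. Overall accuracy is trace/total. Macro averages are
unweighted means across classes. Metrics with a zero denominator are
reported as 0 with a warning, matching how never-predicted classes appear
as 0.00 rows in published reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn.network import Network, stable_softmax

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "classification_metrics",
    "evaluate",
]


@dataclass
class ConfusionMatrix:
    """N×N counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix counts must be non-negative")
        if self.class_names is None:
            self.class_names = [str(i) for i in range(self.counts.shape[0])]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.counts, index=self.class_names, columns=self.class_names
        ).to_csv(path)

    def plot(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(self.counts, cmap="Blues")
        ax.set_xticks(range(len(self.class_names)))
        ax.set_yticks(range(len(self.class_names)))
        ax.set_xticklabels(self.class_names, rotation=90, fontsize=7)
        ax.set_yticklabels(self.class_names, fontsize=7)
        ax.set_xlabel("Predicted")
        ax.set_ylabel("True")
        for i in range(self.counts.shape[0]):
            for j in range(self.counts.shape[1]):
                ax.text(j, i, str(self.counts[i, j]), ha="center", va="center", fontsize=6)
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


@dataclass
class MetricsReport:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    class_names: list[str] = field(default_factory=list)
    undefined_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": [
                {
                    "class": self.class_names[i],
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "support": int(self.support[i]),
                }
                for i in range(len(self.class_names))
            ],
            "undefined_classes": list(self.undefined_classes),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_text(self) -> str:
        """Plain-text table: one P/R/F1 (support) row per class, 3 decimals."""
        width = max([len(c) for c in self.class_names] + [10])
        lines = [f"{'Class':<{width}}  {'P':>6} {'R':>6} {'F1':>6} {'(support)':>9}"]
        for i, name in enumerate(self.class_names):
            lines.append(
                f"{name:<{width}}  {self.precision[i]:6.3f} {self.recall[i]:6.3f} "
                f"{self.f1[i]:6.3f} {'(' + str(int(self.support[i])) + ')':>9}"
            )
        lines.append(
            f"{'Macro-avg.':<{width}}  {self.macro_precision:6.3f} "
            f"{self.macro_recall:6.3f} {self.macro_f1:6.3f}"
        )
        lines.append(f"Accuracy: {self.accuracy:.3f}")
        return "\n".join(lines)


def confusion_matrix(true_labels, predicted_labels, num_classes: int,
                     class_names: list[str] | None = None) -> ConfusionMatrix:
    """Tally counts[i][j] = #{samples with true class i predicted as j}."""
    y = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if y.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for name, v in (("true", y), ("predicted", p)):
        if v.size and (v.min() < 0 or v.max() >= num_classes):
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (y, p), 1)
    return ConfusionMatrix(counts=counts, class_names=class_names)


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class and macro precision/recall/F1 plus overall accuracy from a
    confusion matrix."""
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(counts).astype(np.float64)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    undefined = []
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2.0 * precision * recall / (precision + recall),
            0.0,
        )
    for c in range(counts.shape[0]):
        if tp[c] + fp[c] == 0 or tp[c] + fn[c] == 0:
            undefined.append(c)
    if undefined:
        logger.warning(
            "classes %s have an undefined precision or recall (zero denominator); "
            "reported as 0",
            undefined,
        )
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        support=counts.sum(axis=1),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        accuracy=float(tp.sum() / counts.sum()),
        class_names=list(cm.class_names),
        undefined_classes=undefined,
    )


def evaluate(
    model: Network,
    images: np.ndarray,
    labels: np.ndarray,
    indices: np.ndarray | None = None,
    class_names: list[str] | None = None,
    batch_size: int = 32,
) -> tuple[MetricsReport, ConfusionMatrix]:
    """Run inference on a held-out split and report argmax-vs-truth metrics."""
    x = np.asarray(images, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if indices is not None:
        indices = np.asarray(indices, dtype=np.int64)
        if indices.size == 0:
            raise ValueError("evaluation split is empty")
        x, y = x[indices], y[indices]
    if x.shape[0] == 0:
        raise ValueError("evaluation split is empty")
    preds = []
    for start in range(0, x.shape[0], batch_size):
        probs = stable_softmax(model.forward(x[start : start + batch_size], training=False))
        preds.append(probs.argmax(axis=1))
    preds = np.concatenate(preds)
    n_classes = model.spec.num_classes if hasattr(model, "spec") else int(y.max()) + 1
    cm = confusion_matrix(y, preds, n_classes, class_names=class_names)
    return classification_metrics(cm), cm
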