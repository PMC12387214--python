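"""Imbalance-aware data pipeline for class-foldered fundus image trees.

Stages, in the order the screening workflow applies them: load and resize
to 150×150 RGB in [0,1]; balance every class to the majority count with
SMOTE in flattened pixel space; split 70/15/15 with per-class stratification;
augment training batches on the fly with mild geometric transforms.

Balancing runs *before* splitting, so interpolated samples can share source
images across splits; ``stratified_split`` can equally be applied first by
callers who prefer leak-free evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from skimage.transform import AffineTransform, warp
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}

__all__ = [
    "DatasetBundle",
    "SmoteConfig",
    "SplitBundle",
    "AugmentationConfig",
    "load_dataset",
    "smote_balance",
    "stratified_split",
    "augment_batch",
]


@dataclass
class DatasetBundle:
    """Image stack n×H×W×3 in [0,1], integer labels, ordered class names and
    a per-file manifest (path, class_name, class_index)."""

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    manifest: pd.DataFrame

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels, minlength=len(self.class_names))
        return {name: int(c) for name, c in zip(self.class_names, counts)}


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_count: int | str = "majority"
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if isinstance(self.target_count, str) and self.target_count != "majority":
            raise ValueError("target_count must be 'majority' or an integer")


@dataclass
class SplitBundle:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "train": self.train.tolist(),
            "val": self.val.tolist(),
            "test": self.test.tolist(),
            "fractions": list(self.fractions),
            "seed": self.seed,
        }


@dataclass
class AugmentationConfig:
    """Ranges for on-the-fly training augmentation; each image gets an
    independent draw per epoch. Angles in degrees, shifts/zoom as fractions
    of the image size."""

    rotation_deg: float = 20.0
    shift_frac: float = 0.10
    shear_frac: float = 0.10
    zoom_frac: float = 0.10
    horizontal_flip: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_deg", "shift_frac", "shear_frac", "zoom_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0
            and self.shift_frac == 0
            and self.shear_frac == 0
            and self.zoom_frac == 0
            and not self.horizontal_flip
        )


def load_dataset(root_dir: str | Path, target_size: int = 150) -> DatasetBundle:
    """Load a one-subdirectory-per-class image tree.

    Every decodable image is converted to RGB, resized bilinearly to
    ``target_size``² and scaled by 1/255. Class indices follow the sorted
    class-directory names; undecodable files are skipped with a warning,
    an empty class directory is an error.
    """
    root = Path(root_dir)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    class_names = [p.name for p in class_dirs]
    images, labels, rows = [], [], []
    for idx, cdir in enumerate(class_dirs):
        files = sorted(
            p for p in cdir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
        )
        loaded = 0
        for f in files:
            try:
                with Image.open(f) as im:
                    arr = np.asarray(
                        im.convert("RGB").resize(
                            (target_size, target_size), Image.BILINEAR
                        ),
                        dtype=np.float64,
                    )
            except (UnidentifiedImageError, OSError) as exc:
                logger.warning("skipping undecodable image %s: %s", f, exc)
                continue
            images.append(arr / 255.0)
            labels.append(idx)
            rows.append({"path": str(f), "class_name": cdir.name, "class_index": idx})
            loaded += 1
        if loaded == 0:
            raise ValueError(f"class directory {cdir.name!r} contains no decodable images")
    return DatasetBundle(
        images=np.stack(images),
        labels=np.asarray(labels, dtype=np.int64),
        class_names=class_names,
        manifest=pd.DataFrame(rows),
    )


def smote_balance(
    flat_features: np.ndarray,
    labels: np.ndarray,
    config: SmoteConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority oversampling.

    Each synthetic sample is ``x + u·(x′ − x)`` with ``u`` drawn uniformly in
    (0,1) (one scalar per sample), ``x`` a uniformly chosen member of the
    minority class and ``x′`` one of its ``k`` nearest same-class neighbors
    under the Euclidean metric. Originals are preserved unchanged and come
    first in the output; every class ends at the target count (the majority
    count by default).
    """
    config = config or SmoteConfig()
    x = np.asarray(flat_features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("flat_features must be n×d with one label per row")
    rng = np.random.default_rng(config.seed)
    counts = np.bincount(y)
    present = np.flatnonzero(counts)
    target = (
        int(counts.max())
        if config.target_count == "majority"
        else int(config.target_count)
    )
    new_x, new_y = [x], [y]
    for cls in present:
        n_cls = int(counts[cls])
        deficit = target - n_cls
        if deficit <= 0:
            continue
        if n_cls < 2:
            raise ValueError(
                f"class {cls} has a single sample; SMOTE cannot interpolate"
            )
        k = config.k_neighbors
        if k > n_cls - 1:
            logger.warning(
                "class %d has %d samples; clipping k_neighbors from %d to %d",
                cls,
                n_cls,
                k,
                n_cls - 1,
            )
            k = n_cls - 1
        members = x[y == cls]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(members)
        # drop self-neighbor in column 0
        neighbor_idx = nn.kneighbors(members, return_distance=False)[:, 1:]
        seeds = rng.integers(0, n_cls, size=deficit)
        picks = rng.integers(0, k, size=deficit)
        u = rng.random(deficit)
        u = np.clip(u, np.finfo(np.float64).tiny, None)  # open interval (0,1)
        base = members[seeds]
        neighbor = members[neighbor_idx[seeds, picks]]
        new_x.append(base + u[:, None] * (neighbor - base))
        new_y.append(np.full(deficit, cls, dtype=np.int64))
    return np.concatenate(new_x), np.concatenate(new_y)


def stratified_split(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitBundle:
    """Partition indices into train/val/test preserving class proportions.

    Allocation uses largest-remainder rounding at two levels: the global
    split totals are fixed first, then each class's floor allocations are
    topped up one sample at a time toward the split with the largest global
    deficit. Per-class fractions are exact to ±1 sample and the three parts
    partition the index set.
    """
    y = np.asarray(labels, dtype=np.int64)
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = y.shape[0]
    counts = np.bincount(y)
    for cls in np.flatnonzero(counts):
        if counts[cls] < 3:
            raise ValueError(
                f"class {cls} has {counts[cls]} samples; at least 3 are needed "
                "to appear in all three splits"
            )
    # global targets by largest remainder (ties favor later splits: test, val)
    raw = [n * f for f in fractions]
    targets = [int(np.floor(r)) for r in raw]
    remainders = [r - t for r, t in zip(raw, targets)]
    for _ in range(n - sum(targets)):
        j = max(range(3), key=lambda i: (remainders[i], i))
        targets[j] += 1
        remainders[j] = -1.0
    rng = np.random.default_rng(seed)
    classes = list(np.flatnonzero(counts))
    bases, rems = {}, {}
    for cls in classes:
        m = int(counts[cls])
        raw_c = [m * f for f in fractions]
        bases[cls] = [int(np.floor(r)) for r in raw_c]
        rems[cls] = [r - b for r, b in zip(raw_c, bases[cls])]
    # how many leftover samples each split still needs to reach its total
    extra = [targets[j] - sum(bases[cls][j] for cls in classes) for j in range(3)]
    for cls in classes:
        leftovers = int(counts[cls]) - sum(bases[cls])
        used: set[int] = set()
        for _ in range(leftovers):
            # at most one leftover per split per class keeps each class's
            # fractions within +-1 sample of the targets
            candidates = [j for j in range(3) if extra[j] > 0 and j not in used]
            if not candidates:
                candidates = [j for j in range(3) if extra[j] > 0]
            j = max(candidates, key=lambda i: (rems[cls][i], extra[i], i))
            bases[cls][j] += 1
            extra[j] -= 1
            used.add(j)
    alloc = {0: [], 1: [], 2: []}
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        start = 0
        for j in range(3):
            alloc[j].append(idx[start : start + bases[cls][j]])
            start += bases[cls][j]
    train, val, test = (np.sort(np.concatenate(alloc[j])) for j in range(3))
    return SplitBundle(train=train, val=val, test=test, fractions=fractions, seed=seed)


def _augment_one(img: np.ndarray, config: AugmentationConfig, rng: np.random.Generator):
    h, w = img.shape[:2]
    angle = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
    shear = rng.uniform(-config.shear_frac, config.shear_frac)
    zoom = 1.0 + rng.uniform(-config.zoom_frac, config.zoom_frac)
    tx = rng.uniform(-config.shift_frac, config.shift_frac) * w
    ty = rng.uniform(-config.shift_frac, config.shift_frac) * h
    flip = config.horizontal_flip and rng.random() < 0.5
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tform = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=angle, shear=shear, scale=(zoom, zoom))
        + AffineTransform(translation=center + np.array([tx, ty]))
    )
    out = warp(img, tform.inverse, order=1, mode="edge", preserve_range=True)
    if flip:
        out = out[:, ::-1, :]
    return np.clip(out, 0.0, 1.0)


def augment_batch(
    images: np.ndarray,
    config: AugmentationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Apply independent random geometric transforms to each image.

    Rotation, width/height shift, shear and zoom are drawn uniformly within
    the configured ranges; horizontal flip with probability 0.5. Bilinear
    interpolation with nearest-edge fill; output clipped to [0,1] with
    shapes unchanged. Deterministic for a fixed generator state.
    """
    config = config or AugmentationConfig()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))
    images = np.asarray(images, dtype=np.float64)
    if config.is_identity():
        return images.copy()
    return np.stack([_augment_one(img, config, rng) for img in images])
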