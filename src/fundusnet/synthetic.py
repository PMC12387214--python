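"""Procedural fundus-like image generator.

Renders a circular retinal field (radial brightness falloff, optic disc,
two vessel arcs, pixel noise) and plants one caricature lesion program per
disease class: a swollen bright disc for disc edema, a pale cupped disc for
glaucoma, scattered dark-red dots for diabetic retinopathy, peripheral
pigment speckle for retinitis pigmentosa, a corner wedge for pterygium, a
central serous blister ring, a pale macular scar patch, tessellated texture
for myopia, a pale detached fold sector, and a clean field for healthy eyes.

The lesions are deliberately cartoonish: they make the ten classes
separable by a small classifier and give every image a recorded lesion
bounding region for saliency-containment checks — they are not clinically
realistic. Default per-class counts follow the study dataset's imbalance
profile (largest class 1509, rarest 17, 5335 images in total).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ClassRecipe",
    "GeneratorConfig",
    "DEFAULT_CLASS_COUNTS",
    "DEFAULT_RECIPES",
    "generate_image",
    "generate_dataset",
]

# Four counts are the published ones; the six others are plausible values
# chosen once so the total is 5335.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "central_serous_chorioretinopathy": 101,
    "diabetic_retinopathy": 1509,
    "disc_edema": 218,
    "glaucoma": 1349,
    "healthy": 570,
    "macular_scar": 277,
    "myopia": 479,
    "pterygium": 17,
    "retinal_detachment": 294,
    "retinitis_pigmentosa": 521,
}


@dataclass
class ClassRecipe:
    """A class name plus the lesion program that renders its hallmark.

    ``localized`` marks programs that plant one compact lesion whose bounding
    region is a meaningful saliency target; diffuse programs (scattered dots,
    peripheral speckle, global texture, clean field) record the whole
    retinal field instead.
    """

    class_name: str
    lesion_program: str
    localized: bool


DEFAULT_RECIPES: dict[str, ClassRecipe] = {
    name: ClassRecipe(name, program, localized)
    for name, program, localized in [
        ("central_serous_chorioretinopathy", "central_blister", True),
        ("diabetic_retinopathy", "scattered_dark_spots", False),
        ("disc_edema", "swollen_bright_disc", True),
        ("glaucoma", "cupped_disc", True),
        ("healthy", "clean_field", False),
        ("macular_scar", "central_pale_patch", True),
        ("myopia", "tessellated_texture", False),
        ("pterygium", "corner_wedge", True),
        ("retinal_detachment", "pale_peripheral_fold", True),
        ("retinitis_pigmentosa", "peripheral_speckle", False),
    ]
}


@dataclass
class GeneratorConfig:
    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    image_size: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        for name, count in self.class_counts.items():
            if name not in DEFAULT_RECIPES:
                raise ValueError(f"unknown class {name!r}")
            if count < 2:
                raise ValueError(
                    f"class {name!r} needs at least 2 images (SMOTE requirement)"
                )

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())


def _gauss(yy, xx, cy, cx, sigma):
    return np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))


def _bbox_from_mask(mask: np.ndarray) -> list[int]:
    ys, xs = np.nonzero(mask)
    return [int(ys.min()), int(ys.max()) + 1, int(xs.min()), int(xs.max()) + 1]


def _render_base(s: int, rng: np.random.Generator):
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy = cx = (s - 1) / 2.0
    radius = 0.48 * s
    d = np.hypot(yy - cy, xx - cx)
    fieldmask = d <= radius
    falloff = np.clip(1.0 - 0.6 * (d / radius) ** 2, 0.0, 1.0)
    tint = np.array([0.80, 0.42, 0.22]) * (1.0 + rng.normal(0.0, 0.03, 3))
    img = falloff[..., None] * np.clip(tint, 0.05, 1.0)
    # optic disc, nasal side
    disc_cy = cy + rng.normal(0.0, 0.015) * s
    disc_cx = cx + (0.22 + rng.normal(0.0, 0.01)) * s
    disc_sigma = 0.045 * s
    img += _gauss(yy, xx, disc_cy, disc_cx, disc_sigma)[..., None] * np.array(
        [0.14, 0.17, 0.08]
    )
    # two vessel arcs leaving the disc
    t = np.linspace(0.0, 1.0, 40)
    for sign in (1.0, -1.0):
        py = disc_cy + sign * (0.06 + 0.30 * t**1.5) * s
        px = disc_cx - t * 0.55 * s
        acc = np.full((s, s), np.inf)
        for qy, qx in zip(py, px):
            acc = np.minimum(acc, (yy - qy) ** 2 + (xx - qx) ** 2)
        w = np.exp(-acc / (2.0 * (0.008 * s) ** 2))
        img -= w[..., None] * np.array([0.18, 0.13, 0.07])
    img += rng.normal(0.0, 0.012, (s, s, 1))
    img[~fieldmask] = 0.02
    geometry = {
        "cy": cy, "cx": cx, "radius": radius,
        "disc_cy": disc_cy, "disc_cx": disc_cx, "disc_sigma": disc_sigma,
        "macula_cy": cy + rng.normal(0.0, 0.01) * s,
        "macula_cx": cx - (0.16 + rng.normal(0.0, 0.01)) * s,
    }
    return img, fieldmask, (yy, xx), geometry


def _apply_program(program, img, fieldmask, grids, geo, s, rng):
    """Render a lesion program in place; returns its weight mask (H×W)."""
    yy, xx = grids
    if program == "clean_field":
        return None
    if program == "swollen_bright_disc":
        w = _gauss(yy, xx, geo["disc_cy"], geo["disc_cx"], 0.13 * s)
        img += w[..., None] * np.array([0.50, 0.46, 0.30])
        return w > 0.1
    if program == "cupped_disc":
        w = _gauss(yy, xx, geo["disc_cy"], geo["disc_cx"], 0.065 * s)
        cup = _gauss(yy, xx, geo["disc_cy"], geo["disc_cx"], 0.035 * s)
        img += w[..., None] * np.array([0.20, 0.22, 0.12])
        img += cup[..., None] * np.array([0.55, 0.58, 0.62])
        return w > 0.1
    if program == "scattered_dark_spots":
        # fixed per-class layout of dot slots, jittered per sample, so the
        # class stays compact in pixel space while individual images differ
        total = np.zeros((s, s))
        angles = np.linspace(0.0, 2 * np.pi, 14, endpoint=False)
        radii = np.tile([0.30, 0.55, 0.75], 5)[:14]
        for ang, rad in zip(angles, radii):
            ang = ang + rng.normal(0.0, 0.05)
            rad = (rad + rng.normal(0.0, 0.015)) * geo["radius"]
            cy = geo["cy"] + rad * np.sin(ang)
            cx = geo["cx"] + rad * np.cos(ang)
            w = _gauss(yy, xx, cy, cx, rng.uniform(0.02, 0.028) * s)
            img -= w[..., None] * np.array([0.55, 0.32, 0.16])
            total = np.maximum(total, w)
        return total > 0.3
    if program == "peripheral_speckle":
        total = np.zeros((s, s))
        angles = np.linspace(0.0, 2 * np.pi, 48, endpoint=False)
        radii = np.tile([0.62, 0.75, 0.88], 16)
        for ang, rad in zip(angles, radii):
            ang = ang + rng.normal(0.0, 0.03)
            rad = (rad + rng.normal(0.0, 0.01)) * geo["radius"]
            cy = geo["cy"] + rad * np.sin(ang)
            cx = geo["cx"] + rad * np.cos(ang)
            w = _gauss(yy, xx, cy, cx, rng.uniform(0.008, 0.014) * s)
            img -= w[..., None] * np.array([0.45, 0.40, 0.30])
            total = np.maximum(total, w)
        return total > 0.3
    if program == "corner_wedge":
        apex_x = geo["cx"] - 0.05 * s + rng.normal(0, 0.02) * s
        apex_y = geo["cy"] + rng.normal(0, 0.03) * s
        slope = 0.55 + rng.normal(0, 0.05)
        wedge = (xx <= apex_x) & (np.abs(yy - apex_y) <= slope * (apex_x - xx))
        w = wedge & fieldmask
        img[w] = 0.25 * img[w] + 0.75 * np.array([0.72, 0.62, 0.58])
        return w
    if program == "central_blister":
        r0 = (0.11 + rng.normal(0, 0.008)) * s
        d = np.hypot(yy - geo["macula_cy"], xx - geo["macula_cx"])
        ring = np.exp(-((d - r0) ** 2) / (2.0 * (0.018 * s) ** 2))
        interior = np.clip(1.0 - d / r0, 0.0, 1.0)
        img += ring[..., None] * np.array([0.30, 0.30, 0.25])
        img += interior[..., None] * np.array([0.10, 0.10, 0.08])
        return d <= r0 * 1.4
    if program == "central_pale_patch":
        total = np.zeros((s, s))
        for _ in range(int(rng.integers(4, 7))):
            cy = geo["macula_cy"] + rng.normal(0, 0.03) * s
            cx = geo["macula_cx"] + rng.normal(0, 0.03) * s
            w = _gauss(yy, xx, cy, cx, rng.uniform(0.05, 0.075) * s)
            total = np.maximum(total, w)
        img += total[..., None] * np.array([0.60, 0.58, 0.46])
        return total > 0.12
    if program == "tessellated_texture":
        period = (0.075 + rng.normal(0, 0.0008)) * s
        phase1, phase2 = rng.normal(0.0, 0.07, 2)
        texture = 1.0 + 0.24 * np.sin(2 * np.pi * xx / period + phase1) * np.sin(
            2 * np.pi * yy / period + phase2
        )
        img *= np.where(fieldmask, texture, 1.0)[..., None]
        return fieldmask.copy()
    if program == "pale_peripheral_fold":
        theta = np.arctan2(yy - geo["cy"], xx - geo["cx"])
        theta0 = -2.4 + rng.normal(0, 0.15)
        d = np.hypot(yy - geo["cy"], xx - geo["cx"])
        sector = (
            (theta >= theta0)
            & (theta <= theta0 + 2.2)
            & (d >= 0.25 * geo["radius"])
            & (d <= 1.0 * geo["radius"])
        )
        w = sector & fieldmask
        img[w] = 0.35 * img[w] + 0.65 * np.array([0.66, 0.66, 0.60])
        # fold line: bright arc inside the sector
        mid = 0.62 * geo["radius"]
        arc = np.exp(-((d - mid) ** 2) / (2.0 * (0.015 * s) ** 2)) * w
        img += arc[..., None] * np.array([0.20, 0.20, 0.18])
        return w
    raise ValueError(f"unknown lesion program {program!r}")


def generate_image(
    recipe: ClassRecipe, seed: int, size: int = 150
) -> tuple[np.ndarray, dict]:
    """Render one image for a recipe; returns (image in [0,1], lesion region).

    The region dict records the lesion bounding box as 0-based half-open
    pixel intervals ``[y0, y1, x0, x1]`` and whether the program is
    localized. Deterministic for a fixed (recipe, seed, size).
    """
    rng = np.random.default_rng(seed)
    img, fieldmask, grids, geo = _render_base(size, rng)
    mask = _apply_program(recipe.lesion_program, img, fieldmask, grids, geo, size, rng)
    img = np.clip(img, 0.0, 1.0)
    if mask is None or not mask.any():
        bbox = _bbox_from_mask(fieldmask)
        localized = False
    else:
        bbox = _bbox_from_mask(mask & fieldmask if mask.dtype == bool else mask)
        localized = recipe.localized
    return img, {"bbox": bbox, "localized": localized, "class_name": recipe.class_name}


def generate_dataset(
    config: GeneratorConfig | None = None,
    out_dir: str | Path = "synthetic_fundus",
    force: bool = False,
) -> pd.DataFrame:
    """Write a class-foldered PNG tree with manifest CSV and lesion-region
    sidecar JSON; refuses a non-empty output directory unless ``force``."""
    config = config or GeneratorConfig()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"{out} is not empty; pass force=True to write into it anyway"
        )
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    rows, regions = [], {}
    for name in sorted(config.class_counts):
        recipe = DEFAULT_RECIPES[name]
        cdir = out / name
        cdir.mkdir(exist_ok=True)
        for i in range(config.class_counts[name]):
            img_seed = int(master.integers(0, 2**31 - 1))
            img, region = generate_image(recipe, img_seed, config.image_size)
            rel = f"{name}/{name}_{i:05d}.png"
            Image.fromarray((img * 255).round().astype(np.uint8)).save(out / rel)
            rows.append({"path": rel, "class_name": name})
            regions[rel] = region
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "lesions.json").write_text(json.dumps(regions))
    return manifest
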