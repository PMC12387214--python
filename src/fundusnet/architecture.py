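"""The attention-augmented screening CNN: declarative spec, builder, accounting.

The network is a compact hierarchical feature extractor for 150×150×3 fundus
photographs: a 64-filter stem, four blocks widening 64→128→256→512→1024
(depthwise-separable convolutions gated by squeeze-and-excitation or
global-context attention in blocks 1–3, a projected residual block in
block 4), 2×2 max-pooling between blocks, then a global-average-pooled dense
head (1024 → 512 units, dropout 0.5) and a softmax output. With the default
specification the model holds 16,552,114 trainable and 8,960 non-trainable
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (
    BatchNorm,
    Conv2D,
    Dense,
    DepthwiseConv2D,
    Dropout,
    GCBlock,
    GlobalAveragePool,
    MaxPool2x2,
    Network,
    ReLU,
    ResidualBlock,
    SEBlock,
    Sequential,
)
from .nn.network import stable_softmax

__all__ = [
    "ArchitectureSpec",
    "LayerParamRecord",
    "ParamSummary",
    "build_model",
    "count_parameters",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ArchitectureSpec:
    """Declarative description of the network.

    ``attention_plan`` assigns one tag per block: ``"se"`` or ``"gc"`` puts a
    depthwise-separable convolution plus that channel-attention gate in the
    block; ``"residual"`` uses a projected residual block instead.
    """

    input_height: int = 150
    input_width: int = 150
    input_channels: int = 3
    stem_filters: int = 64
    block_channels: tuple[int, ...] = (128, 256, 512, 1024)
    se_reduction: int = 16
    dense_units: tuple[int, ...] = (1024, 512)
    dropout_rate: float = 0.5
    num_classes: int = 10
    attention_plan: tuple[str, ...] = ("se", "gc", "se", "residual")
    bn_momentum: float = 0.99

    def __post_init__(self):
        self.block_channels = tuple(int(c) for c in self.block_channels)
        self.dense_units = tuple(int(u) for u in self.dense_units)
        self.attention_plan = tuple(self.attention_plan)
        counts = (
            self.input_height,
            self.input_width,
            self.input_channels,
            self.stem_filters,
            self.se_reduction,
            self.num_classes,
            *self.block_channels,
            *self.dense_units,
        )
        if any(int(c) <= 0 for c in counts):
            raise ValueError("all architecture counts must be positive")
        if len(self.block_channels) != 4:
            raise ValueError("block_channels must list exactly 4 blocks")
        if len(self.attention_plan) != len(self.block_channels):
            raise ValueError("attention_plan must tag every block")
        bad = set(self.attention_plan) - {"se", "gc", "residual"}
        if bad:
            raise ValueError(f"unknown attention tags: {sorted(bad)}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.bn_momentum < 1.0:
            raise ValueError("bn_momentum must be in (0, 1)")
        # every SE gate needs a squeeze width of at least one unit
        widths = [self.stem_filters, *self.block_channels]
        for i, tag in enumerate(self.attention_plan):
            if tag == "se" and widths[i + 1] // self.se_reduction < 1:
                raise ValueError(
                    f"block {i + 1}: SE squeeze width floor("
                    f"{widths[i + 1]}/{self.se_reduction}) is 0"
                )

    def spatial_trace(self) -> list[tuple[int, int]]:
        """Spatial dims after the stem pool and each block pool."""
        h, w = self.input_height, self.input_width
        trace = []
        for _ in range(len(self.block_channels) + 1):
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ValueError("input too small for five 2×2 pooling stages")
            trace.append((h, w))
        return trace

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown architecture keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class LayerParamRecord:
    name: str
    trainable: int
    non_trainable: int


@dataclass
class ParamSummary:
    trainable: int
    non_trainable: int
    total: int
    trainable_mem_mib: float
    non_trainable_mem_kib: float
    per_layer: list[LayerParamRecord] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [f"{'Layer':<28}{'Trainable':>14}{'Non-trainable':>16}"]
        lines.append("-" * 58)
        for rec in self.per_layer:
            lines.append(f"{rec.name:<28}{rec.trainable:>14,}{rec.non_trainable:>16,}")
        lines.append("-" * 58)
        lines.append(f"{'Trainable':<28}{self.trainable:>14,}  {self.trainable_mem_mib:.2f} MB")
        lines.append(
            f"{'Non-trainable':<28}{self.non_trainable:>14,}  {self.non_trainable_mem_kib:.2f} KB"
        )
        lines.append(f"{'Total':<28}{self.total:>14,}")
        return "\n".join(lines)


def _ds_attention_block(name, cin, cout, tag, reduction, rng, bn_momentum):
    layers = [
        DepthwiseConv2D("dw", cin, rng=rng),
        BatchNorm("dw_bn", cin, momentum=bn_momentum),
        ReLU("dw_relu"),
        Conv2D("pw", cin, cout, 1, rng=rng),
        BatchNorm("pw_bn", cout, momentum=bn_momentum),
        ReLU("pw_relu"),
    ]
    if tag == "se":
        layers.append(SEBlock("se", cout, reduction, rng=rng))
    else:
        layers.append(GCBlock("gc", cout, rng=rng))
    return Sequential(name, layers)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> Network:
    """Build the network with He-initialized kernels, zero biases, unit BN.

    The returned :class:`~fundusnet.nn.Network` exposes tap points at every
    block output: pre-pool (``block4``: H/16 spatial) and post-pool
    (``block4_pool``), the two candidate layers for class-activation maps.
    """
    spec.spatial_trace()  # validates spatial feasibility
    rng = np.random.default_rng(seed)
    stages: list[tuple[str, object]] = [
        (
            "stem",
            Sequential(
                "stem",
                [
                    Conv2D("conv", spec.input_channels, spec.stem_filters, 3, rng=rng),
                    BatchNorm("bn", spec.stem_filters, momentum=spec.bn_momentum),
                    ReLU("relu"),
                ],
            ),
        ),
        ("stem_pool", MaxPool2x2("stem_pool")),
    ]
    cin = spec.stem_filters
    for i, (cout, tag) in enumerate(zip(spec.block_channels, spec.attention_plan), start=1):
        name = f"block{i}"
        if tag == "residual":
            block = ResidualBlock(name, cin, cout, rng=rng, bn_momentum=spec.bn_momentum)
        else:
            block = _ds_attention_block(
                name, cin, cout, tag, spec.se_reduction, rng, spec.bn_momentum
            )
        stages.append((name, block))
        stages.append((f"{name}_pool", MaxPool2x2(f"{name}_pool")))
        cin = cout
    stages.append(("gap", GlobalAveragePool("gap")))
    width = cin
    for j, units in enumerate(spec.dense_units, start=1):
        stages.append(
            (
                f"head{j}",
                Sequential(
                    f"head{j}",
                    [
                        Dense("fc", width, units, rng=rng),
                        ReLU("relu"),
                        Dropout("drop", spec.dropout_rate),
                    ],
                ),
            )
        )
        width = units
    stages.append(("output", Dense("output", width, spec.num_classes, rng=rng)))

    net = Network(stages)
    net.spec = spec
    net.tap_points = [f"block{i}" for i in range(1, 5)] + ["block4_pool"]
    net.default_cam_layer = "block4"
    net.l2_penalized = [f"head{j}.fc.w" for j in range(1, len(spec.dense_units) + 1)]
    return net


def _leaf_layers(layer, prefix=""):
    name = f"{prefix}{layer.name}"
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _leaf_layers(sub, prefix=f"{name}.")
    elif isinstance(layer, ResidualBlock):
        for sub in layer._sublayers():
            yield from _leaf_layers(sub, prefix=f"{name}.")
    else:
        yield name, layer


def count_parameters(model: Network) -> ParamSummary:
    """Exact per-layer integer accounting; memory at 4 bytes per parameter
    (trainable reported in MiB, non-trainable in KiB, both to 2 decimals)."""
    records = []
    for _, stage in model.stages:
        for name, leaf in _leaf_layers(stage):
            t, nt = leaf.param_counts()
            if t or nt:
                records.append(LayerParamRecord(name, t, nt))
    trainable = sum(r.trainable for r in records)
    non_trainable = sum(r.non_trainable for r in records)
    return ParamSummary(
        trainable=trainable,
        non_trainable=non_trainable,
        total=trainable + non_trainable,
        trainable_mem_mib=round(trainable * 4 / 2**20, 2),
        non_trainable_mem_kib=round(non_trainable * 4 / 1024, 2),
        per_layer=records,
    )


def forward(model: Network, batch: np.ndarray) -> np.ndarray:
    """Inference forward pass: image batch B×H×W×3 in [0,1] → class
    probabilities B×N (rows sum to 1)."""
    spec = model.spec
    expected = (spec.input_height, spec.input_width, spec.input_channels)
    if batch.ndim != 4 or batch.shape[1:] != expected:
        raise ValueError(f"expected batch of shape (B, {expected}), got {batch.shape}")
    return stable_softmax(model.forward(np.asarray(batch, dtype=np.float64), training=False))


def save_checkpoint(model: Network, path: str | Path) -> None:
    """Write weights as .npz plus a JSON sidecar with the architecture spec
    and per-layer parameter summary."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.get_weights())
    summary = count_parameters(model)
    sidecar = {
        "architecture": model.spec.to_dict(),
        "parameters": {
            "trainable": summary.trainable,
            "non_trainable": summary.non_trainable,
            "total": summary.total,
            "per_layer": [asdict(r) for r in summary.per_layer],
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> Network:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec_dict = sidecar["architecture"]
    spec_dict["block_channels"] = tuple(spec_dict["block_channels"])
    spec_dict["dense_units"] = tuple(spec_dict["dense_units"])
    spec_dict["attention_plan"] = tuple(spec_dict["attention_plan"])
    model = build_model(ArchitectureSpec.from_dict(spec_dict))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.set_weights({k: data[k] for k in data.files})
    return model
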