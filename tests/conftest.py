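import numpy as np
import pytest

from fundusnet import ArchitectureSpec, GeneratorConfig, generate_dataset, load_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_tree(tmp_path_factory):
    """A small generated class-foldered image tree (10 classes × 6, 48 px)."""
    root = tmp_path_factory.mktemp("tiny_fundus")
    cfg = GeneratorConfig(
        class_counts={name: 6 for name in GeneratorConfig().class_counts},
        image_size=48,
        seed=7,
    )
    generate_dataset(cfg, root, force=True)
    return root


@pytest.fixture(scope="session")
def tiny_bundle(tiny_tree):
    return load_dataset(tiny_tree, target_size=48)


@pytest.fixture
def small_spec():
    """A narrow architecture for fast tests (32 px input)."""
    return ArchitectureSpec(
        input_height=32,
        input_width=32,
        stem_filters=4,
        block_channels=(8, 8, 8, 16),
        se_reduction=2,
        dense_units=(16, 8),
        num_classes=10,
        dropout_rate=0.0,
        bn_momentum=0.8,
    )
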