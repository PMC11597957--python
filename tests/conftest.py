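import numpy as np
import pytest

from pawmoco import SyntheticConfig, generate_synthetic_emotion_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """7 balanced classes, 8 images each, 32 px, strong class signal."""
    cfg = SyntheticConfig(n_classes=7, n_per_class=8, image_size=32,
                          signal_strength=0.9, nuisance_strength=0.3, seed=7)
    return generate_synthetic_emotion_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """3 classes x 6 images, written as a class-per-folder PNG tree."""
    out = tmp_path_factory.mktemp("tinytree")
    cfg = SyntheticConfig(n_classes=3, n_per_class=6, image_size=32,
                          signal_strength=0.9, nuisance_strength=0.2, seed=11)
    generate_synthetic_emotion_dataset(cfg, out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
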