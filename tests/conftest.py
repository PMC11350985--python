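import warnings

import numpy as np
import pytest

from retinograde.labels import GradeLabel, JOINT_CLASSES
from retinograde.preprocess import (
    denoise_reconstruct,
    dwt2_multilevel,
    equalize_histogram,
    to_green_channel,
)
from retinograde.synthetic import GeneratorConfig, generate_dataset

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def small_dataset(gen_config):
    """24 synthetic fundus samples (3 per joint class), generated once."""
    samples, manifest = generate_dataset(gen_config, 24)
    return samples, manifest


@pytest.fixture(scope="session")
def preprocessed_dataset(gen_config, small_dataset):
    samples, _ = small_dataset
    size = (gen_config.image_size, gen_config.image_size)
    out = []
    for s in samples:
        eq = equalize_histogram(to_green_channel(s.image, size))
        out.append(denoise_reconstruct(dwt2_multilevel(eq), rule="soft", threshold=8.0))
    return out


@pytest.fixture(scope="session")
def segmenter(small_dataset, preprocessed_dataset):
    """A small trained segmenter shared across segmentation tests."""
    from retinograde.segment import train_segmenter

    samples, _ = small_dataset
    return train_segmenter(
        samples[:16],
        preprocessed_dataset[:16],
        n_hidden=24,
        per_class=3000,
        max_iter=400,
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def all_labels():
    return list(JOINT_CLASSES)
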