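import logging

import numpy as np
import pytest

from ricemap.grid import RasterGrid
from ricemap.pipeline import identify_rice
from ricemap.simulate import (
    DEFAULT_TRAINING_COUNTS,
    DEFAULT_VALIDATION_COUNTS,
    SceneConfig,
    generate_scene,
    sample_points,
)

logging.getLogger("ricemap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_scene():
    """The reference desk-scale scene at its default configuration."""
    return generate_scene(SceneConfig(seed=0))


@pytest.fixture(scope="session")
def default_samples(default_scene):
    train = sample_points(default_scene, DEFAULT_TRAINING_COUNTS, "training", seed=0)
    val = sample_points(
        default_scene, DEFAULT_VALIDATION_COUNTS, "validation", seed=0,
        training_counts=DEFAULT_TRAINING_COUNTS,
    )
    return train, val


@pytest.fixture(scope="session")
def default_result(default_scene, default_samples):
    train, _ = default_samples
    return identify_rice(
        default_scene.optical, default_scene.sar, default_scene.dem,
        default_scene.config.calendar, train,
    )


@pytest.fixture(scope="session")
def small_scene():
    """A fast 96x96 scene for unit-level pipeline tests."""
    return generate_scene(SceneConfig(size=96, n_rice_patches=10, seed=0))


@pytest.fixture(scope="session")
def small_samples(small_scene):
    train_counts = {"rice": 30, "water": 20, "built-up": 20,
                    "natural-vegetation": 20, "dry-land": 20}
    val_counts = {"rice": 20, "water": 10, "built-up": 10,
                  "natural-vegetation": 10, "dry-land": 10}
    train = sample_points(small_scene, train_counts, "training", seed=0)
    val = sample_points(small_scene, val_counts, "validation", seed=0,
                        training_counts=train_counts)
    return train, val


@pytest.fixture
def grid32():
    return RasterGrid(width=32, height=32)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
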