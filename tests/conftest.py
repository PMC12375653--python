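"""Shared fixtures: small synthetic scenes generated at test time."""

import numpy as np
import pytest

from needlespec.hsi_core import paper_grid
from needlespec.rgb_synthesis import render_rgb
from needlespec.synthetic_scene import SceneConfig, generate_dataset


@pytest.fixture(scope="session")
def grid():
    return paper_grid()


@pytest.fixture(scope="session")
def small_dataset():
    """12 noisy 64×64 scenes with default distortions."""
    cfg = SceneConfig(seed=7)
    cubes, masks, labels = generate_dataset(12, cfg)
    return cfg, cubes, masks, labels


@pytest.fixture(scope="session")
def clean_scene():
    """One noiseless, scatter-free 64×64 scene plus its rendered RGB."""
    cfg = SceneConfig(seed=3, noise_sd=0.0, scatter_mult=(1.0, 1.0),
                      scatter_add=(0.0, 0.0))
    cubes, masks, labels = generate_dataset(10, cfg)
    rgb = render_rgb(cubes[0]).values
    return cubes[0], masks[0], labels.iloc[0], rgb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
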