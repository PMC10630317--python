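import warnings

import numpy as np
import pytest

from fibranet import synthetic
from fibranet.segmentation import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_network():
    """A moderately dense unconstrained network with ground truth."""
    spec = synthetic.NetworkSpec(n_fibers=14, seed=11)
    return spec, *synthetic.generate_fiber_network(spec)


@pytest.fixture
def sparse_network():
    """A constraint-sampled network on which every crossing is resolvable."""
    spec = synthetic.NetworkSpec(n_fibers=10, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = synthetic.generate_sparse_network(spec)
    return spec, *out


def make_bar_mask(thickness_px=3, length_px=100, pixel_size=0.1, pad=20):
    h = thickness_px + 2 * pad
    w = length_px + 2 * pad
    grid = np.zeros((h, w), dtype=bool)
    grid[pad:pad + thickness_px, pad:pad + length_px] = True
    return BinaryMask(grid=grid, pixel_size=pixel_size)


def make_plus_mask(arm_px=30, thickness_px=3, pixel_size=0.1, pad=20):
    size = 2 * (arm_px + pad) + thickness_px
    c = arm_px + pad
    grid = np.zeros((size, size), dtype=bool)
    grid[c:c + thickness_px, pad:size - pad] = True
    grid[pad:size - pad, c:c + thickness_px] = True
    return BinaryMask(grid=grid, pixel_size=pixel_size)
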