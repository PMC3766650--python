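import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tacsquant import FiberSceneParams, ProjectedImage
from tacsquant.stacks import Channel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """Small, fast scene used by tests that only need structural validity."""
    return FiberSceneParams(
        image_size_px=(64, 64),
        n_slices=3,
        n_fibers=8,
        fiber_length_um_mean=40.0,
        fiber_length_um_sd=8.0,
        noise_sd=2.0,
        background_offset=5.0,
        seed=7,
    )


def as_image(pixels, channel=Channel.IF, pixel_size_um=1.0, **kw):
    return ProjectedImage(pixels=np.asarray(pixels, dtype=float), channel=channel,
                          pixel_size_um=pixel_size_um, **kw)


@pytest.fixture
def make_image():
    return as_image
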