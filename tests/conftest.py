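import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py

from gliamorph import synthetic as syn


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disk_class():
    """Round cell with no processes (amoeboid-like), fixed-ish size."""
    return syn.ShapeClass("disk", (10.0, 13.0), (0, 0), (0.0, 0.0),
                          (0.0, 0.0), (1.0, 1.1))


@pytest.fixture(scope="session")
def star4_class():
    """Four-armed star (ramified-like)."""
    return syn.ShapeClass("star4", (6.0, 8.0), (4, 4), (16.0, 20.0),
                          (2.5, 3.0))


@pytest.fixture(scope="session")
def noiseless_field():
    """Noise-free 20-cell synthetic field with ground truth."""
    spec = syn.SyntheticSpec(image_shape=(512, 512), n_cells=20,
                             noise_sd=0.0, seed=7)
    image, truth = syn.generate_image(spec)
    return spec, image, truth


def raster_disk(radius: int, pad: int = 10) -> np.ndarray:
    """Binary disk of exact radius (pixel centers within distance r)."""
    size = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
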