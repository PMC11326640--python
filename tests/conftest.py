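import numpy as np
import pytest

from sfdiff.diffusion import train_diffusion
from sfdiff.fixtures import ShapeSpec, binarize_pairs, make_dataset, make_shape

#: Study conditions for the scaled-down end-to-end runs: 64 px rasters at
#: 2.2 um/px, cell areas spanning the fixture default up to the largest
#: shape that fits the raster, aspect ratios 1-5.
TINY_DATASET = dict(resolution=64, pixel_size=2.2, area=(1.2e3, 2.0e3),
                    aspect_ratio=(1.0, 5.0))
TINY_SEED = 42
N_TRAIN = 190


@pytest.fixture(scope="session")
def tiny_pairs():
    """195 binary-label synthetic pairs: 190 training + 5 held out."""
    return binarize_pairs(
        make_dataset(195, shape_ranges=TINY_DATASET, seed=TINY_SEED)
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_pairs):
    """Conditional diffusion generator trained once per session (tiny profile)."""
    return train_diffusion(tiny_pairs[:N_TRAIN], profile="tiny")


@pytest.fixture()
def disk_cell():
    return make_shape(
        ShapeSpec(kind="ellipse", aspect_ratio=1.0, area=np.pi * 40**2,
                  resolution=128, pixel_size=1.0)
    )
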