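import numpy as np
import pytest

from metaspread.synthetic import SyntheticSpec, generate_field


@pytest.fixture(scope="session")
def clean_field():
    """Noise-free 10-chromosome field: every chromosome bears a FISH spot,
    4 of 10 are colocalized (offsets 6 / 30 px)."""
    spec = SyntheticSpec(
        n_chromosomes=10,
        image_shape=(512, 512),
        fish_spot_fraction=1.0,
        coloc_fraction=0.4,
        noise_sd=0.0,
        seed=7,
    )
    return generate_field(spec)


@pytest.fixture(scope="session")
def noisy_field():
    """Field at 10:1 spot amplitude to read-noise ratio."""
    spec = SyntheticSpec(
        n_chromosomes=16,
        image_shape=(512, 512),
        fish_spot_fraction=1.0,
        coloc_fraction=0.5,
        spot_amplitude=2000.0,
        noise_sd=200.0,
        seed=11,
    )
    return generate_field(spec)


@pytest.fixture
def rod_mask():
    """One horizontal 9x40 rod labelled 1 in a 64x96 frame."""
    mask = np.zeros((64, 96), dtype=np.int32)
    mask[28:37, 20:60] = 1
    return mask


def make_blobs(*rects, shape=(64, 96)):
    """Label mask with one axis-aligned rectangle per (r0, r1, c0, c1)."""
    mask = np.zeros(shape, dtype=np.int32)
    for label, (r0, r1, c0, c1) in enumerate(rects, start=1):
        mask[r0:r1, c0:c1] = label
    return mask
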