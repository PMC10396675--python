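import numpy as np
import pytest

from focalseg.synthetic_data import PhantomSpec, generate_slice


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """Phantom spec sized for fast tests (64 px, ranges scaled down)."""
    return PhantomSpec(
        image_size=64,
        n_slices=4,
        nodule_diameter_range_benign=(4.0, 7.0),
        nodule_diameter_range_malignant=(9.0, 14.0),
        vessel_count=2,
        noise_sigma=4.0,
        seed=99,
    )


@pytest.fixture
def clean_disc_spec():
    """One noise-free benign disc, no vessels."""
    return PhantomSpec(
        image_size=64,
        n_slices=1,
        benign_fraction=1.0,
        nodule_diameter_range_benign=(8.0, 12.0),
        nodule_diameter_range_malignant=(16.0, 20.0),
        vessel_count=0,
        noise_sigma=0.0,
        seed=5,
    )


@pytest.fixture
def one_slice(small_spec):
    return generate_slice(small_spec, 0)


def random_binary_mask(rng, shape=(16, 16), p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)
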