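import numpy as np
import pytest

from petseg_consensus import PhantomSpec, StudyConfig


@pytest.fixture
def two_level_image():
    """Sharp noise-free phantom: cuboid lesion (value 10) on background 1."""
    img = np.ones((12, 14, 14))
    obj = np.zeros_like(img, dtype=bool)
    obj[4:8, 4:10, 5:10] = True
    img[obj] = 10.0
    init = np.zeros_like(obj)
    init[2:10, 2:12, 3:12] = True
    return img, obj, init


@pytest.fixture
def small_spec():
    """A compact phantom spec for fast simulation tests."""
    return PhantomSpec(shape=(32, 64, 64), lesion_volume_cm3=8.0, seed=7)


@pytest.fixture(scope="session")
def clean_study_config():
    """One-case, effectively noise-free, homogeneous-lesion study."""
    return StudyConfig(
        n_cases=1,
        seed=11,
        motion=False,
        phantom_overrides=dict(
            shape=(32, 64, 64),
            level_fractions=(1.0, 0.0, 0.0),
            noise_scale=1e7,
            psf_fwhm_mm=2.0,
            post_filter_fwhm_mm=0.5,
        ),
    )
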