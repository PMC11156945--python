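import numpy as np
import pytest

from olfatau.imaging_io import VolumeSet
from olfatau.synthetic_data import CohortSpec, generate_cohort, make_synthetic_atlas


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(n_subjects=60, seed=7))


@pytest.fixture(scope="session")
def atlas():
    return make_synthetic_atlas(shape=(20, 20, 20), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def noise_volume(rng):
    shape = (8, 8, 8)
    data = rng.standard_normal((20, *shape))
    return VolumeSet(data=data, affine=np.diag([2.0, 2.0, 2.0, 1.0]), mask=np.ones(shape, bool))
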