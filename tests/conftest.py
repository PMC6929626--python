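import numpy as np
import pytest

from betaquant import phantom
from betaquant.mr_quant import AcquisitionParams


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec(rng_seed=7)


@pytest.fixture(scope="session")
def noisefree_spec():
    return phantom.PhantomSpec(
        rng_seed=7, noise_sigma_mr=0.0, noise_sigma_pet=0.0,
        noise_sigma_autorad=0.0, noise_sigma_msi=0.0,
    )


@pytest.fixture(scope="session")
def label_map(default_spec):
    return phantom.build_label_map(default_spec)


@pytest.fixture(scope="session")
def acq_two_angle():
    return AcquisitionParams(flip_deg=(4.0, 22.0))


@pytest.fixture(scope="session")
def acq_three_angle():
    return AcquisitionParams(flip_deg=(4.0, 14.0, 27.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
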