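from dataclasses import replace

import numpy as np
import pytest

from myodti import PhantomSpec, default_scheme, simulate_dwi
from myodti.tensor_model import eigen_maps, fit_tensor_field

SMALL_SHAPE = (32, 32, 16)


@pytest.fixture(scope="session")
def scheme():
    """17 directions at b = 400 s/mm^2 plus three b = 0 volumes."""
    return default_scheme()


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(seed=42, shape=SMALL_SHAPE)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    """Noisy (SNR 59) healthy-preset phantom on a small grid."""
    return simulate_dwi(small_spec)


@pytest.fixture(scope="session")
def clean_subject():
    """Effectively noise-free, fat-free phantom: ground-truth oracle."""
    base = PhantomSpec(seed=42, shape=SMALL_SHAPE, snr=1e9)
    muscles = tuple(replace(m, ff=0.0) for m in base.resolve_muscles())
    return simulate_dwi(replace(base, muscles=muscles))


@pytest.fixture(scope="session")
def clean_field(clean_subject):
    mask = clean_subject.labels.labels > 0
    return fit_tensor_field(
        clean_subject.dwi, clean_subject.scheme, mask=mask, robust=False
    )


@pytest.fixture(scope="session")
def clean_maps(clean_field):
    return eigen_maps(clean_field)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
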