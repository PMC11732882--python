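import numpy as np
import pytest

from cordox.forward import AcquisitionConfig, build_array
from cordox.spectra import load_default_extinction


@pytest.fixture(scope="session")
def extinction():
    return load_default_extinction()


@pytest.fixture(scope="session")
def small_array():
    """Desk-scale spherical cap: 96 elements, instrument radius/coverage."""
    return build_array(n_elements=96, radius=40.0, coverage_deg=110.0, seed=0)


@pytest.fixture()
def acq_single_wl():
    return AcquisitionConfig(n_samples=1600, wavelengths=(800.0,), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
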