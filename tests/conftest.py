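import numpy as np
import pytest

from mirqc import (
    QCConfig,
    derive_co2_reference,
    derive_water_vapor_reference,
    simulate_background_pair,
    simulate_spectrum,
)


@pytest.fixture(scope="session")
def cfg():
    return QCConfig()


@pytest.fixture(scope="session")
def ref_co2():
    pair = simulate_background_pair(seed=1, wv_delta=0.02, co2_delta=0.2)
    return derive_co2_reference(pair)


@pytest.fixture(scope="session")
def ref_wv(ref_co2):
    pair = simulate_background_pair(seed=2, wv_delta=0.25, co2_delta=0.05)
    return derive_water_vapor_reference(pair, ref_co2)


@pytest.fixture(scope="session")
def clean_spectrum():
    """Default noiseless organic-matter spectrum on the 650-3999 integer grid."""
    s, _ = simulate_spectrum()
    return s


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
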