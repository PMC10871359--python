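import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def three_state_model():
    from smfretq.kinetics import KineticModel

    return KineticModel.default_three_state()


@pytest.fixture(scope="session")
def snr10_photophysics():
    from smfretq.fixtures import photophysics_for_snr

    return photophysics_for_snr(10.0)
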