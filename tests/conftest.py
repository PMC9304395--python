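import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mechamap import AcquisitionConfig, QCConfig

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    """Default acquisition settings (20 pN force noise)."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def acq_noiseless() -> AcquisitionConfig:
    return AcquisitionConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def qc_config() -> QCConfig:
    return QCConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
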