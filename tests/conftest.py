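import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from atassay import OpticalConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def optics() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250630)
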