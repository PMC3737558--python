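import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(autouse=True)
def _quiet_tau_warnings():
    # Short diagnostic series legitimately trip the tau length warning.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="series length",
                                category=RuntimeWarning)
        yield


@pytest.fixture
def geom():
    from ringmix import ConfinementGeometry

    return ConfinementGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
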