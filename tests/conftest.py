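import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20231103)


@pytest.fixture
def moderate_tables():
    """The three reconstructed app-vs-reference moderate-loss ear tables."""
    from audioscreen import TwoByTwo

    return {
        "tdh39": TwoByTwo(1, 7, 0, 80),
        "dt770": TwoByTwo(1, 5, 0, 82),
        "generic": TwoByTwo(1, 6, 0, 81),
    }
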