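import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_geometry():
    from hexallee import HexGeometry

    return HexGeometry(n_cols=12, n_rows=12)


@pytest.fixture
def allee():
    from hexallee import strong_allee_growth

    return strong_allee_growth(0.4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
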