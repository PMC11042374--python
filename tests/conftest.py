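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
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    from hybridbarriers.panel import make_panel

    return make_panel(2, 40, 1.0, seed=1)


@pytest.fixture(scope="session")
def chapul_spec():
    """Study-conditions population spec (two-cluster hybrid population)."""
    from hybridbarriers.simulate import PopulationSpec

    return PopulationSpec()
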