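import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microstates import SimulationConfig, ifcn25, make_canonical_templates

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage():
    return ifcn25()


@pytest.fixture(scope="session")
def canonical(montage):
    return make_canonical_templates(montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_config():
    """Two 10 s epochs: enough dynamics to test with, fast to simulate."""
    return SimulationConfig(n_epochs=2, epoch_s=10.0)
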