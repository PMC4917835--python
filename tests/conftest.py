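import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from molprice.synthetic import GeneratorConfig, generate_catalog

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog_small():
    """A 20k-record default-config catalogue shared across tests."""
    frame, ground_truth = generate_catalog(GeneratorConfig(n=20_000, seed=42))
    return frame, ground_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
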