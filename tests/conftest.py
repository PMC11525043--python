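import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from mutualink import (NullModelConfig, SyntheticCommunityConfig,  # noqa: E402
                       generate_community)


@pytest.fixture(scope="session")
def small_config():
    """Desk-test community small enough for exhaustive checks."""
    return SyntheticCommunityConfig(n_sites=25, n_plants=8, n_butterflies=5,
                                    connectance_target=0.3, coupling=2.0, seed=42)


@pytest.fixture(scope="session")
def small_community(small_config):
    return generate_community(small_config)


@pytest.fixture(scope="session")
def fast_null_config():
    return NullModelConfig(n_randomizations=100, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
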