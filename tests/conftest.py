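import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom64():
    """Shared textured phantom: 64 px, 1.5 Å/px."""
    from aberro.simulate import make_phantom

    return make_phantom(64, 1.5, n_blobs=14, seed=7)


@pytest.fixture(scope="session")
def phantom32():
    from aberro.simulate import make_phantom

    return make_phantom(32, 1.5, n_blobs=10, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
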