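import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def background_g():
    """A skewed 5-class folded background spectrum for n = 10."""
    from ayescan.sfs_stats import FoldedSFS

    return FoldedSFS(10, np.array([0.5, 0.3, 0.1, 0.06, 0.04]))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)
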