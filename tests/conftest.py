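import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def valid_dm(rng):
    """A realizable (Gram) dissimilarity matrix over the four conditions."""
    from stereorsa.core import pearson_distance_matrix
    return pearson_distance_matrix(rng.standard_normal((4, 8)))
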