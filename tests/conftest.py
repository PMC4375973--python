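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

from csisd import summary_from_scalars


@pytest.fixture
def protein_g_ca_summary():
    """The printed Protein G Cα summary: n = 54, χ² = 69.7 ppm²."""
    return summary_from_scalars({"CA": (54, 69.7)})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
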