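import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hemri import CohortConfig, generate_study
from hemri import analytes as panel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default 4x150 synthetic cohort, shared across tests."""
    cfg = CohortConfig(random_seed=20190601)
    return generate_study(cfg, panel.default_analytes())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
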