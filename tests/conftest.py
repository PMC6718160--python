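import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from scarid.synthetic_data import SimConfig, simulate_population  # noqa: E402


@pytest.fixture(scope="session")
def default_sample():
    """One landing-style sample at generator defaults."""
    cfg = SimConfig(n_fish=455, seed=42)
    fish, otoliths = simulate_population(cfg)
    return cfg, fish, otoliths


@pytest.fixture(scope="session")
def stratified_sample():
    """Ageing-subsample design: every age class represented, no selectivity."""
    cfg = SimConfig(
        n_fish=400,
        seed=7,
        age_distribution="uniform",
        selectivity=None,
        reader_error_sd=0.0,
    )
    fish, otoliths = simulate_population(cfg)
    return cfg, fish, otoliths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
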