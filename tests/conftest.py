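import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hlatyper import SimConfig, simulate_allele_db

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_panel():
    """Default synthetic panel: quartets and one near-duplicate pair per gene."""
    cfg = SimConfig(seed=11, depth=90.0)
    db, meta = simulate_allele_db(cfg)
    return cfg, db, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
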