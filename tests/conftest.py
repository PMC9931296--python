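import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from seizewear.simulate import SimConfig, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_subject():
    """One deterministic 2-hour synthetic subject shared across tests."""
    cfg = SimConfig(duration_hours=2.0, seed=42)
    record, truth = generate_subject(cfg, 0)
    return cfg, record, truth
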