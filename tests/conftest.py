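import numpy as np
import pytest

from takeoffkit import ScenarioConfig, simulate_trip


@pytest.fixture(scope="session")
def default_trip():
    """One clean default-scenario trip shared across read-only tests."""
    cfg = ScenarioConfig(seed=7)
    dep, truth = simulate_trip(cfg)
    return cfg, dep, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
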