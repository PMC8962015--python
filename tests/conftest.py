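import numpy as np
import pytest

from wgsflow import ScenarioConfig


@pytest.fixture
def scenario() -> ScenarioConfig:
    return ScenarioConfig.default()


@pytest.fixture
def small_scenario() -> ScenarioConfig:
    """Default world, short horizon: fast enough for per-test simulation."""
    return ScenarioConfig.default().with_override("run.horizon_days", 300.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
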