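import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mtgrowth import (
    CALIBRATED_PARAMS,
    GMPCPP,
    LatticeConfig,
    LatticeState,
    SolutionState,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def plus_config() -> LatticeConfig:
    return LatticeConfig(polarity="plus")


@pytest.fixture
def minus_config() -> LatticeConfig:
    return LatticeConfig(polarity="minus")


@pytest.fixture
def blunt_plus(plus_config) -> LatticeState:
    return LatticeState.blunt_seed(plus_config)


@pytest.fixture
def calibrated_params():
    return CALIBRATED_PARAMS


@pytest.fixture
def cpp_solution() -> SolutionState:
    return SolutionState(tubulin_total=1.25, strong_species=GMPCPP)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
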