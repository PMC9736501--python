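import numpy as np
import pytest

from graspnirs.pipeline import PipelineConfig
from graspnirs.simulate import SimulationParams, simulate_study


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A small but otherwise default-protocol study: 6 subjects, 10 channels."""
    return SimulationParams(n_epd=3, n_mpd=3, n_channels=10)


@pytest.fixture(scope="session")
def small_study(small_params):
    return simulate_study(small_params, seed=101)


@pytest.fixture(scope="session")
def small_config(small_params) -> PipelineConfig:
    return PipelineConfig(sim=small_params, seed=101)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
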