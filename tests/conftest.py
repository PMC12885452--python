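import numpy as np
import pandas as pd
import pytest

from swmediate.panel import ModelSpec, attach_baseline
from swmediate.synthdata import SimulationConfig, generate_trial


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down trial (57 participants) for fast unit tests."""
    return SimulationConfig(cluster_sizes=(12, 8, 10, 12, 9, 6), seed=12345)


@pytest.fixture(scope="session")
def small_panel(small_config) -> pd.DataFrame:
    return generate_trial(small_config)


@pytest.fixture(scope="session")
def small_panel_baseline(small_panel) -> pd.DataFrame:
    return attach_baseline(small_panel, "pss")


@pytest.fixture
def pss_spec() -> ModelSpec:
    return ModelSpec.for_outcome("pss", ["cd_risc"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)
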