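import numpy as np
import pytest

from meltplex import (
    PanelConfig,
    SimulationConfig,
    default_prototype_panel,
    simulate_well,
)


@pytest.fixture(scope="session")
def panel() -> PanelConfig:
    return default_prototype_panel()


@pytest.fixture(scope="session")
def small_panel(panel) -> PanelConfig:
    """Prototype panel shrunk to 2,048 partitions for fast tests."""
    data = panel.model_dump(mode="json")
    data["partitions_per_well"] = 2048
    data["normalization"] = {"window_size": 201}
    return PanelConfig.model_validate(data)


@pytest.fixture(scope="session")
def blank_well(panel):
    cfg = SimulationConfig(panel=panel, seed=3)
    table, truth = simulate_well(cfg)
    return table, truth


@pytest.fixture(scope="session")
def small_blank_well(small_panel):
    cfg = SimulationConfig(panel=small_panel, seed=3)
    table, truth = simulate_well(cfg)
    return table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
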