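import numpy as np
import pandas as pd
import pytest

from exmort import MortalityPanel, SimulationConfig, generate_panel


@pytest.fixture
def small_panel():
    """10 weeks x 3 causes, deterministic integer counts."""
    rng = np.random.default_rng(7)
    counts = rng.integers(50, 150, size=(10, 3))
    dates = pd.date_range("2020-01-04", periods=10, freq="7D")
    return MortalityPanel(dates, counts, ["C1", "C2", "C3"])


@pytest.fixture
def study_shaped_panel():
    """Synthetic panel with the study's shape: 194 weeks x 14 causes."""
    return generate_panel(SimulationConfig(n_weeks=194, seed=11))


def make_config(**overrides):
    """Small 3-cause simulation config; overrides applied on top."""
    defaults = dict(
        n_weeks=200,
        causes=["A", "B", "C"],
        baseline=[500.0, 800.0, 300.0],
        trend=0.0,
        yearly_amplitude=0.0,
        yearly_phase=0.0,
        dispersion=100.0,
        seed=1,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
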