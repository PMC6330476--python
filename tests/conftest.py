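import numpy as np
import pytest

from destab import CountMatrix, GroupDesign, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cm():
    """4 features x 4 samples with mixed magnitudes, no all-zero feature."""
    counts = np.array(
        [
            [10, 14, 30, 26],
            [100, 120, 40, 50],
            [0, 1, 2, 0],
            [5, 5, 5, 5],
        ]
    )
    return CountMatrix(counts, ["g1", "g2", "g3", "g4"], ["a1", "a2", "b1", "b2"])


@pytest.fixture
def small_design():
    return GroupDesign(["A", "A", "B", "B"])


@pytest.fixture(scope="session")
def basic_dataset():
    """One scaled-down dataset from the default study design (G=2000, 3v3)."""
    cfg = SimulationConfig(n_features=2000, n_per_group=3, seed=1)
    cm, design, truth, mask = simulate_dataset(cfg)
    return cm, design, truth
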