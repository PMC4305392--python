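import numpy as np
import pytest

from chromaggr.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic dataset shared across tests (seed fixed)."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """A light config for tests that re-simulate repeatedly."""
    return SimulationConfig(
        seed=3,
        chrom_sizes={"chr1": 400_000},
        state_layout={
            "active promoter": (6, 2000),
            "weak promoter": (6, 2000),
            "inactive promoter": (6, 2000),
            "enhancer state 4": (4, 1600),
        },
        fe_map={
            "active promoter": 4.0,
            "weak promoter": 1.5,
            "inactive promoter": 1.0,
            "enhancer state 4": 3.0,
        },
        n_genes=5,
        n_peaks=60,
    )
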