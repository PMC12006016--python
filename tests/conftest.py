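import numpy as np
import pandas as pd
import pytest

from trajgex import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def null_sim():
    """40 subjects, 500 genes, no age signal anywhere."""
    cfg = SimulationConfig(
        n_subjects=40,
        n_genes=500,
        archetype_props={"NULL": 1.0},
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def mixed_sim():
    """Default desk-scale design at 1000 genes: 10% dynamic over six shapes."""
    return simulate_dataset(SimulationConfig(n_genes=1000, seed=7))


@pytest.fixture(scope="session")
def tiny_sim():
    """Small dataset for I/O and CLI round trips."""
    return simulate_dataset(SimulationConfig(n_subjects=12, n_genes=60, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
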