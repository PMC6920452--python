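import numpy as np
import pytest

from haplospatial import (ContingencyMatrix, SimulationConfig,
                          simulate_coi_dataset, simulate_full_matrix)


@pytest.fixture(scope="session")
def paper_scale_template() -> ContingencyMatrix:
    """A fully observed 25 x 11 haplotype-by-location table of 226 counts."""
    return simulate_full_matrix(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_matrix() -> ContingencyMatrix:
    return ContingencyMatrix(np.array([[3, 1], [1, 3]]),
                             ("Hap_01", "Hap_02"), ("north", "south"))


@pytest.fixture(scope="session")
def coi_dataset():
    """Simulated 548-bp amplicon survey with 10% NUMT-like decoys."""
    config = SimulationConfig(seed=11)
    return simulate_coi_dataset(config, decoy_rate=0.1)
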