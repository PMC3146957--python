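import numpy as np
import pytest

from pinemap.simulate import SimulationConfig, simulate_cross, simulate_genome


@pytest.fixture(scope="session")
def clean_config():
    return SimulationConfig(seed=42, n_offspring=200, error_rate=0.0, missing_rate=0.0)


@pytest.fixture(scope="session")
def small_genome(clean_config):
    # one 60 cM group, 6 markers evenly spaced
    return simulate_genome(
        clean_config,
        n_groups=1,
        group_lengths_cM=[60.0],
        n_markers=6,
        positions=[(0, 12.0 * i) for i in range(6)],
    )


@pytest.fixture(scope="session")
def cp_matrix(small_genome, clean_config):
    return simulate_cross(small_genome, clean_config, "CP")


@pytest.fixture(scope="session")
def f2_matrix(small_genome, clean_config):
    return simulate_cross(small_genome, clean_config, "F2")
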