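import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from genefam.simulate import SimulationConfig, simulate_family, simulate_genome


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def family_fixture(sim_config):
    return simulate_family(sim_config)


@pytest.fixture(scope="session")
def genome_fixture(sim_config):
    return simulate_genome(sim_config)
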