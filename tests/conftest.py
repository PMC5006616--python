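import pytest

from ltrscape.structural_detect import call_structural_elements
from ltrscape.synthetic_data import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def sim():
    """Default desk-scale simulated genome (2 Mb, 10 SIEs, 50 fragments)."""
    return simulate_genome(SimulationConfig())


@pytest.fixture(scope="session")
def detected(sim):
    """Structural elements called on the default simulated genome."""
    return call_structural_elements(sim.genome, trna_set=sim.trnas)
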