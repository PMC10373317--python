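import pytest

from ltrkit.ltr_detect import detect_elements
from ltrkit.sim_genome import SimConfig, simulate_genome


SMALL_CONFIG = dict(
    genome_length=300_000,
    n_intact=6,
    n_solo=4,
    n_solo_without_tsd=2,
    n_truncated=2,
    n_genes=5,
    seed=1,
)


@pytest.fixture(scope="session")
def small_sim():
    """A 300-kb synthetic genome shared across tests (read-only)."""
    return simulate_genome(SimConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_elements(small_sim):
    """Detected elements on the small genome, classified from domain hits."""
    return detect_elements(small_sim.genome, domain_hits=small_sim.domain_hits)
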