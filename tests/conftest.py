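import pytest

from paleokaryo import SimulationConfig, simulate_dataset
from paleokaryo.model import SpeciesTree

FIVE_TAXON_NEWICK = "(((At:7,Al:7)A1:6,Cr:13)ACK:14,(Br:12,Tp:12)PCK:15)ABK;"


@pytest.fixture(scope="session")
def brassica_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(FIVE_TAXON_NEWICK)


@pytest.fixture(scope="session")
def quiet_dataset():
    """A small zero-rate simulation: every genome equals the root."""
    cfg = SimulationConfig(
        seed=11,
        n_chromosomes=3,
        genes_per_chromosome=40,
        inversion_rate=0.0,
        translocation_rate=0.0,
        fusion_rta_rate=0.0,
        fission_rate=0.0,
        gene_gain_rate=0.0,
        gene_loss_rate=0.0,
        hexaploidy=None,
        time_scale=0.2,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def busy_dataset():
    """A desk-scale simulation with all event types and the triplication."""
    cfg = SimulationConfig(seed=3, time_scale=0.2)
    return simulate_dataset(cfg)
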