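import pytest

from phylofam import SpeciesTree, simulate_families, simulate_species_tree
from phylofam.simulate import planted_families, synthesize_hit_table


@pytest.fixture(scope="session")
def stree8():
    """The 8-taxon pure-birth tree used by the simulation-recovery fixtures."""
    return simulate_species_tree(8, 1.0, seed=1)


@pytest.fixture(scope="session")
def stree_abc():
    return SpeciesTree.from_newick("((A,B),C);")


@pytest.fixture(scope="session")
def fams_lossless(stree8):
    return simulate_families(stree8, 200, dup_rate=0.5, loss_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def fams_lossy(stree8):
    return simulate_families(stree8, 200, dup_rate=0.5, loss_rate=0.2, seed=7)


@pytest.fixture(scope="session")
def planted_fixture():
    """10 planted families, 200 proteins, noisy all-vs-all hit table."""
    families = planted_families(n_families=10, n_proteins=200, n_species=10)
    hits, lengths = synthesize_hit_table(families, noise_prob=0.01, seed=3)
    return families, hits, lengths
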