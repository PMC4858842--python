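import numpy as np
import pytest

from mulescout.phylo import SpeciesTree
from mulescout.synthetic import PlantConfig, simulate_genomes


@pytest.fixture(scope="session")
def default_tree():
    return SpeciesTree.default()


@pytest.fixture(scope="session")
def small_sim():
    """11 taxa, 400 kb, 8 species-specific elements/taxon, half captures."""
    cfg = PlantConfig(
        seed=101,
        genome_length=500_000,
        elements_per_taxon=8,
        n_donor_genes=10,
        n_background_genes=10,
        capture_fraction=0.5,
    )
    return simulate_genomes(cfg)


@pytest.fixture(scope="session")
def branch_sim():
    """Two elements on every branch of the default tree (no mutation)."""
    tree = SpeciesTree.default()
    plan = {b: 2 for b in tree.branch_labels}
    cfg = PlantConfig(
        seed=202,
        genome_length=400_000,
        branch_insertions=plan,
        n_donor_genes=8,
        n_background_genes=8,
        capture_fraction=0.5,
        chimera_fraction=0.5,
        chimera_donors=3,
    )
    return simulate_genomes(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
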