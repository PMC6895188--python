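import numpy as np
import pytest

from cerebrotype import PhyloTree, SimConfig, simulate_bundle, simulate_tree


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def star_tree_8():
    """Star phylogeny, 8 tips, unit depths: C equals the identity."""
    tips = ",".join(f"t{i}:1" for i in range(8))
    return PhyloTree.from_newick(f"({tips});")


@pytest.fixture(scope="session")
def yule_tree_12():
    return simulate_tree(12, seed=7)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study reused by the integration-style tests."""
    cfg = SimConfig(n_species=12, n_modes=4, n_genes=90, n_go_terms=6,
                    seed=11)
    return simulate_bundle(cfg)
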