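import pytest

from cladediv.simulate import (
    seedplant_clade_table,
    seedplant_marginal_clade_table,
    sample_family_richness,
    simulate_bd_tree,
)
from cladediv.shifts import BDParams
from cladediv.tree_model import read_newick

TOY_NEWICK = "((A:1,B:1):1,C:2);"
TOY_RICHNESS = {"A": 2.0, "B": 3.0, "C": 1.0}


@pytest.fixture
def toy_tree():
    return read_newick(TOY_NEWICK)


@pytest.fixture
def toy_richness():
    return dict(TOY_RICHNESS)


@pytest.fixture(scope="session")
def seedplant_records():
    """Full-scale tree-backed clade table (425 families, 849 clades)."""
    return seedplant_clade_table(seed=0)


@pytest.fixture(scope="session")
def marginal_records():
    """Clade table drawn from the published age/richness marginals."""
    return seedplant_marginal_clade_table(seed=0)


@pytest.fixture(scope="session")
def small_family_fixture():
    """A 40-ish-tip Yule family tree with model-drawn richness."""
    _, tree = simulate_bd_tree(0.1, 0.0, n_tips=40, seed=11)
    richness = sample_family_richness(tree, BDParams("yule", 0.1), seed=12)
    return tree, richness
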