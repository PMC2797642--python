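import numpy as np
import pytest

from lgtplace.phylo_core import AminoAlignment, PhyloTree, parse_model_spec
from lgtplace.synthetic_data import sample_tree, simulate_alignment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quartet():
    return PhyloTree.from_newick("((A:0.1,B:0.2):0.15,(C:0.1,D:0.3):0.05);")


@pytest.fixture
def poisson_model():
    return parse_model_spec("Poisson")


@pytest.fixture
def wag_gi_model():
    return parse_model_spec("WAG+G+I", alpha=0.7, p_inv=0.15)


@pytest.fixture
def small_case():
    """5-taxon tree with a simulated 12-site alignment under WAG+G+I."""
    tree = sample_tree(5, branch_scale=0.3, seed=7)
    model = parse_model_spec("WAG+G+I", alpha=0.7, p_inv=0.2)
    aln = simulate_alignment(tree, model, 12, seed=3)
    return tree, aln, model


def random_small_tree(rng, ntaxa=None, scale=0.4):
    ntaxa = ntaxa or int(rng.integers(4, 6))
    return sample_tree(ntaxa, branch_scale=scale, seed=int(rng.integers(1 << 30)))
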