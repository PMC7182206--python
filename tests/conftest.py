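import numpy as np
import pytest

from rootedml.models import build_gtr, discretize_rates, jukes_cantor
from rootedml.simgen import SimSpec, random_tree, simulate_alignment
from rootedml.treeio import Alignment, DNA, compress_patterns


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_tree():
    """Six-taxon rooted Yule tree with moderate branch lengths."""
    return random_tree(6, "yule", 0.15, seed=3)


@pytest.fixture
def gtr_model(rng):
    return build_gtr(rng.uniform(0.5, 3.0, 6), rng.dirichlet(np.full(4, 8.0)))


@pytest.fixture
def small_alignment(small_tree):
    spec = SimSpec(tree=small_tree, model=jukes_cantor(),
                   rate_model=discretize_rates(0.8, 0.0, 4),
                   n_sites=600, seed=11)
    return simulate_alignment(spec)


@pytest.fixture
def small_patterns(small_alignment):
    return compress_patterns(small_alignment)


def toy_alignment(seqs: dict) -> Alignment:
    return Alignment(list(seqs), list(seqs.values()), DNA)
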