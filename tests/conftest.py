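import numpy as np
import pytest

from signedrole import SignedNetwork, merge_networks
from signedrole.simulate import make_sim_tree, make_scale_free


@pytest.fixture(scope="session")
def sim_tree():
    return make_sim_tree()


@pytest.fixture(scope="session")
def small_scale_free():
    return make_scale_free(60, 2, 0.3, seed=11)


@pytest.fixture
def path_net():
    """A - B (pos), B - C (neg): simplest mixed-sign path."""
    return SignedNetwork(pos_edges={("A", "B")}, neg_edges={("B", "C")})


@pytest.fixture
def two_context_identical():
    """The same 4-gene network under two context labels."""
    pos = {("A", "B"), ("B", "C")}
    neg = {("C", "D")}
    n1 = SignedNetwork(pos_edges=pos, neg_edges=neg, context="c1")
    n2 = SignedNetwork(pos_edges=pos, neg_edges=neg, context="c2")
    return merge_networks([n1, n2])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
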