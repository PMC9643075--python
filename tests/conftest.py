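import numpy as np
import pytest

import phylorisk as pr


@pytest.fixture(scope="session")
def tree50():
    """A fixed 50-tip Yule tree shared by covariance/likelihood tests."""
    return pr.simulate_tree(50, seed=501)


@pytest.fixture(scope="session")
def cov50(tree50):
    return pr.phylo_covariance(tree50)


@pytest.fixture(scope="session")
def tree20():
    return pr.simulate_tree(20, seed=201)


@pytest.fixture(scope="session")
def star_tree():
    """A 6-tip star phylogeny with unit tip branches (C = I)."""
    newick = "(a:1,b:1,c:1,d:1,e:1,f:1);"
    return pr.read_tree(newick, from_string=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
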