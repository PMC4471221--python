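import numpy as np
import pytest

from cochlevol import synthetic, treeio


@pytest.fixture
def three_tip_tree():
    return treeio.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return treeio.read_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def phylogram22():
    """Non-ultrametric 22-tip tree, fixed seed."""
    return synthetic.simulate_tree(22, "pure-birth", seed=421, jitter_sd=0.3)


@pytest.fixture
def yule22():
    """(Nearly) ultrametric 22-tip pure-birth tree, fixed seed."""
    return synthetic.simulate_tree(22, "pure-birth", seed=421)


@pytest.fixture
def rng():
    return np.random.default_rng(20250903)


def tip_vector(values: dict, tree) -> np.ndarray:
    """Order a {tip: value} dict along the tree's tip order."""
    return np.array([values[l] for l in treeio.tip_labels(tree)])
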