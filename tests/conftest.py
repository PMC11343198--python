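import numpy as np
import pytest

from codiverge.phylo import parse_newick
from codiverge.simulate import SimConfig, simulate_host_tree


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def host_tree4():
    return parse_newick("((h1:1,h2:1):2,(h3:1.5,h4:0.5):1);")


@pytest.fixture
def yule_host_tree():
    return simulate_host_tree(SimConfig(n_hosts=8, rng_seed=77))
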