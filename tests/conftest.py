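import numpy as np
import pytest

from comorbnet import DiseaseNetwork, fig5_toy


@pytest.fixture
def toy():
    """Six-protein toy: graph + seed map (D_A {P2,P3}, D_B {P1}, D_C {P1})."""
    return fig5_toy()


@pytest.fixture
def toy_graph(toy):
    return toy[0]


@pytest.fixture
def toy_seeds(toy):
    return toy[1]


def random_network(rng, n, density=0.4, names=None):
    """Random symmetric weighted network with zero diagonal, weights in (0,1]."""
    W = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(0.05, 1.0, size=len(iu[0])) * mask
    W[iu] = vals
    W = W + W.T
    if names is None:
        names = tuple(f"d{i:03d}" for i in range(n))
    return DiseaseNetwork(names, W, layer_tag="random")
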