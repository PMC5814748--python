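import numpy as np
import pytest

from netsmooth import (ClusterConfig, ExpressionMatrix, GeneNetwork,
                       benchmark_instance, normalize)


@pytest.fixture
def pair_network():
    """Two genes joined by a single undirected edge."""
    return GeneNetwork(["g1", "g2"], {("g1", "g2"): 1.0})


@pytest.fixture
def pair_adjacency(pair_network):
    return normalize(pair_network)


@pytest.fixture
def star_network():
    """Hub h connected to three leaves."""
    edges = {("g1", "h"): 1.0, ("g2", "h"): 1.0, ("g3", "h"): 1.0}
    return GeneNetwork(["h", "g1", "g2", "g3"], edges)


def random_network(n_genes: int, p: float, seed: int) -> GeneNetwork:
    """Erdos-Renyi unsigned network with every gene connected to its
    successor (so no zero-degree nodes)."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    edges = {}
    for i in range(n_genes):
        edges[(genes[i], genes[(i + 1) % n_genes])] = 1.0
        for j in range(i + 2, n_genes):
            if rng.random() < p:
                edges[(genes[i], genes[j])] = float(rng.uniform(0.5, 2.0))
    edges = {(min(u, v), max(u, v)): w for (u, v), w in edges.items() if u != v}
    return GeneNetwork(genes, edges)


@pytest.fixture(scope="session")
def default_dataset():
    return benchmark_instance("default")


@pytest.fixture(scope="session")
def easy_dataset():
    return benchmark_instance("easy")


@pytest.fixture
def random_expression():
    rng = np.random.default_rng(7)
    vals = rng.poisson(5.0, size=(50, 30)).astype(float)
    return ExpressionMatrix(vals, [f"g{i}" for i in range(50)],
                            [f"c{j}" for j in range(30)])


@pytest.fixture
def fast_config():
    return ClusterConfig(seed=3)
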