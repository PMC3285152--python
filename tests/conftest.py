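import numpy as np
import pytest

from pebblegame.fixtures import (
    chain_protein,
    toy_two_hbond_network,
    triangle_network,
)
from pebblegame.network import WeightedNetwork


@pytest.fixture
def triangle():
    return triangle_network()


@pytest.fixture
def toy_topology():
    return toy_two_hbond_network()


@pytest.fixture
def small_chain():
    return chain_protein(6, 0.8, seed=2)


def random_weighted_network(rng: np.random.Generator,
                            max_vertices: int = 6,
                            max_edges: int | None = None,
                            integer: bool | None = None) -> WeightedNetwork:
    """Random small body-bar network for oracle and property tests."""
    n = int(rng.integers(2, max_vertices + 1))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    keep = [p for p in pairs if rng.uniform() < 0.6]
    if max_edges is not None:
        keep = keep[:max_edges]
    edges = []
    for u, v in keep:
        as_int = integer if integer is not None else bool(rng.uniform() < 0.5)
        if as_int:
            cap = float(rng.integers(1, 9))
        else:
            cap = round(float(rng.uniform(0.05, 8.0)), 3)
        edges.append((u, v, cap))
    return WeightedNetwork(n, edges)
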