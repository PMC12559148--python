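import numpy as np
import pytest

import synchropat as sp

# printed 6-cell vulval-precursor-cell adjacency table
VPC_TABLE = [
    [0, 2, 0, 0, 0, 0],
    [1, 0, 1, 0, 0, 0],
    [0, 1, 0, 1, 0, 0],
    [0, 0, 1, 0, 1, 0],
    [0, 0, 0, 1, 0, 1],
    [0, 0, 0, 0, 2, 0],
]

EXAMPLE1_TABLE = [[1, 1, 0], [2, 0, 0], [1, 1, 0]]


@pytest.fixture(scope="session")
def vpc6():
    return sp.build_line_lattice(6)


@pytest.fixture(scope="session")
def example1_net():
    return sp.example1_network()


@pytest.fixture(scope="session")
def torus16():
    return sp.build_periodic_lattice_2d(16, 16, {"nearest": 3, "diagonal": 1})


@pytest.fixture(scope="session")
def vpc_spec(vpc6):
    return sp.adjacency_spectrum(vpc6)


@pytest.fixture(scope="session")
def example1_spec(example1_net):
    return sp.adjacency_spectrum(example1_net)


def random_regular_digraph(rng, n, valence):
    """Random regular directed network without self-arrows.

    Sum of ``valence`` random fixed-point-free permutation matrices:
    every row and column sums to the valence and the diagonal is zero.
    """
    a = np.zeros((n, n), dtype=int)
    for _ in range(valence):
        while True:
            perm = rng.permutation(n)
            if not np.any(perm == np.arange(n)):
                break
        a[np.arange(n), perm] += 1
    return sp.validate_regular(a)


def random_symmetric_regular(rng, n_choices=(4, 6, 8), degree_choices=(2, 3)):
    """Random connected undirected regular graph as a symmetric network."""
    import networkx as nx

    while True:
        n = int(rng.choice(n_choices))
        d = int(rng.choice(degree_choices))
        if (n * d) % 2:
            continue
        g = nx.random_regular_graph(d, n, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return sp.validate_regular(nx.to_numpy_array(g, dtype=int))
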