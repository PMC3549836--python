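"""Shared fixtures and independent scalar oracles."""

import logging

import numpy as np
import pytest

import blockmod as bm

logging.getLogger("blockmod").setLevel(logging.ERROR)


# ---------------------------------------------------------------------------
# independent oracles: plain double-loop evaluations of the definitions,
# kept free of the package's matrix/rank-one code paths
# ---------------------------------------------------------------------------

def scalar_block_matrix(net, tau, q):
    """Loop evaluation of Q_rs = sum_{i != j} (w_ij - p_ij) [tau_i=r][tau_j=s]."""
    W = net.weights.toarray()
    n = net.n
    d = W.sum(axis=1)
    M = d.sum()
    Q = np.zeros((q, q))
    for i in range(n):
        for j in range(n):
            if i != j:
                Q[tau[i], tau[j]] += W[i, j] - d[i] * d[j] / M
    return Q


def scalar_fitness(net, tau, q):
    """Loop evaluation of Q* = ||Q||_L1 / (2M)."""
    W = net.weights.toarray()
    M = W.sum()
    return np.abs(scalar_block_matrix(net, tau, q)).sum() / (2 * M)


def random_er_network(n, p, seed):
    """Erdos-Renyi G(n, p) with at least one edge, unit weights."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, 1)
    while True:
        mask = rng.random(iu.size) < p
        if mask.sum() >= 1:
            pairs = list(zip(iu[mask].tolist(), ju[mask].tolist()))
            return bm.Network.from_edges(
                [f"n{i}" for i in range(n)], pairs, [1.0] * len(pairs))


def random_weighted_network(n, p, seed):
    """ER topology with Uniform(0.5, 2) weights."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, 1)
    while True:
        mask = rng.random(iu.size) < p
        if mask.sum() >= 1:
            pairs = list(zip(iu[mask].tolist(), ju[mask].tolist()))
            w = rng.uniform(0.5, 2.0, size=len(pairs)).tolist()
            return bm.Network.from_edges([f"n{i}" for i in range(n)], pairs, w)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def two_triangles():
    """Two disjoint triangles {0,1,2}, {3,4,5}; q=2 optimum is 7/12."""
    edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
    return bm.Network.from_edges([f"n{i}" for i in range(6)], edges, [1.0] * 6)


@pytest.fixture
def two_triangles_optimum(two_triangles):
    asg = bm.Assignment(np.array([0, 0, 0, 1, 1, 1]), 2)
    nm = bm.null_model(two_triangles)
    return bm.Solution(asg, bm.fitness(two_triangles, nm, asg))


@pytest.fixture
def k22():
    """Complete bipartite K_{2,2}: sides {a,b} and {c,d}; side split Q*=0.375."""
    return bm.Network.from_edges(list("abcd"), [(0, 2), (0, 3), (1, 2), (1, 3)],
                                 [1.0] * 4)


@pytest.fixture
def triangle():
    return bm.Network.from_edges(list("xyz"), [(0, 1), (1, 2), (0, 2)], [1.0] * 3)


@pytest.fixture
def path3():
    """Path a - b - c."""
    return bm.Network.from_edges(list("abc"), [(0, 1), (1, 2)], [1.0] * 2)
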