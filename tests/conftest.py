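"""Shared fixtures: random graph/partition factories and small named graphs."""

import numpy as np
import pytest

from leidenkit import Graph, Partition


def make_random_graph(rng, n, p, weighted=True, self_loops=False):
    """Erdős–Rényi-style graph with optional weights and self-loops."""
    edges = {}
    for u in range(n):
        if self_loops and rng.random() < 0.1:
            edges[(u, u)] = rng.uniform(0.5, 2.0) if weighted else 1.0
        for v in range(u + 1, n):
            if rng.random() < p:
                edges[(u, v)] = rng.uniform(0.5, 2.0) if weighted else 1.0
    return Graph(n, edges)


def make_random_partition(rng, graph, max_communities=None):
    cmax = max_communities or max(2, graph.n // 3)
    return Partition(graph, rng.integers(0, cmax, graph.n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def two_triangles():
    """Two disjoint unit-weight triangles on nodes 0-2 and 3-5."""
    edges = {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0,
             (3, 4): 1.0, (4, 5): 1.0, (3, 5): 1.0}
    return Graph(6, edges)


@pytest.fixture
def two_cliques_weak_bridge():
    """Two 4-cliques joined by a single weight-0.1 edge (3-4)."""
    edges = {}
    for base in (0, 4):
        for a in range(base, base + 4):
            for b in range(a + 1, base + 4):
                edges[(a, b)] = 1.0
    edges[(3, 4)] = 0.1
    return Graph(8, edges)
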