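"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the implementation paths they check:
clique enumeration by testing all 2^n vertex subsets, cut/volume by direct
summation over cliques and pairs, conductance by exhaustive bipartition.
"""

from itertools import combinations

import numpy as np
import pytest

from cliquecond import Graph


def random_graph(rng, n, p):
    """Erdos-Renyi G(n, p) as a cliquecond Graph."""
    edges = [(i, j) for i, j in combinations(range(n), 2) if rng.random() < p]
    return Graph([str(i) for i in range(n)], edges)


def brute_force_maximal_cliques(g):
    """All maximal cliques by checking every vertex subset (n <= ~14)."""
    verts = range(g.n)
    cliques = []
    for k in range(1, g.n + 1):
        for sub in combinations(verts, k):
            if all(v in g.adj[u] for u, v in combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [
        tuple(sorted(c))
        for c in cliques
        if not any(c < other for other in cliques)
    ]
    return set(maximal)


@pytest.fixture
def triangle():
    return Graph(["1", "2", "3"], [(0, 1), (0, 2), (1, 2)])


@pytest.fixture
def k4_minus_edge():
    # vertices 1..4 as indices 0..3; missing edge {1,4} = (0,3)
    return Graph(["1", "2", "3", "4"], [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)])


@pytest.fixture
def bridge_triangles():
    """Two triangles {1,2,3},{4,5,6} joined by the bridge 3-4."""
    from cliquecond.datasets import bridge_of_triangles

    return bridge_of_triangles()


@pytest.fixture
def two_triangles():
    """Two disjoint triangles."""
    return Graph(
        [str(i) for i in range(1, 7)],
        [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)],
    )


@pytest.fixture
def karate():
    from cliquecond.datasets import karate_club

    return karate_club()
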