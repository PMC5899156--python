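"""The induced clique graph and the clique-conductance functionals.

The induced clique graph G_c shares the vertex and edge set of the input
graph G but reweights each edge {u,v} by

    pi_c(u, v) = sum of omega(sigma) over maximal cliques sigma containing
                 both u and v,

so pi_c measures how densely two vertices are tied together through
higher-order structure.  The clique cut of a vertex subset A charges every
maximal clique omega(sigma) for each of its vertex pairs split by (A, Ā);
this equals the ordinary weighted cut of G_c, and likewise the clique volume
equals the weighted volume of G_c (the z^T L_c z identity).  That equality is
what turns clique-conductance minimization into conductance minimization on
a weighted graph, where normalized spectral partitioning applies.

All pi_c weights and cut/volume values are exact integers; floating point
enters only at the final conductance division.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .cliques import MaximalCliqueSet
from .graph import Graph, Partition

__all__ = [
    "CliqueGraph",
    "induced_clique_graph",
    "clique_cut",
    "clique_vol",
    "membership_volume",
    "cut_sum",
    "partition_conductance",
    "partition_conductance_from_cliques",
]


@dataclass
class CliqueGraph:
    """Weighted graph G_c induced by the maximal cliques of a base graph."""

    base: Graph
    weights: dict[tuple[int, int], int]  # unordered (i<j) pair -> pi_c > 0

    def __post_init__(self):
        n = self.base.n
        W = np.zeros((n, n), dtype=np.int64)
        for (u, v), w in self.weights.items():
            W[u, v] = w
            W[v, u] = w
        self.W = W
        self.degrees = W.sum(axis=1)  # diagonal of D_c

    @property
    def n(self) -> int:
        return self.base.n

    def laplacian(self) -> np.ndarray:
        """Combinatorial Laplacian L_c = D_c - W_c (integer matrix)."""
        return np.diag(self.degrees) - self.W

    def total_volume(self) -> int:
        return int(self.degrees.sum())

    def cut(self, A: Iterable[int]) -> int:
        """Weighted cut: sum of pi_c(u,v) over u in A, v outside A."""
        z = _indicator(self.n, A)
        return int(z @ self.W @ (1 - z))

    def vol(self, A: Iterable[int]) -> int:
        """Weighted volume: sum of clique degrees over A."""
        z = _indicator(self.n, A)
        return int(z @ self.degrees)


def _indicator(n: int, A: Iterable[int]) -> np.ndarray:
    z = np.zeros(n, dtype=np.int64)
    for v in A:
        z[v] = 1
    return z


def induced_clique_graph(g: Graph, M: MaximalCliqueSet) -> CliqueGraph:
    """Build G_c from a graph and its maximal-clique set.

    Raises if M is inconsistent with g (an edge of g covered by no clique,
    or a clique pair that is not an edge) — the support of pi_c must equal
    the original edge set.
    """
    if M.n != g.n:
        raise ValueError(f"clique set is over {M.n} vertices, graph has {g.n}")
    weights: dict[tuple[int, int], int] = {}
    for clique in M:
        w = len(clique)
        for a in range(w):
            for b in range(a + 1, w):
                pair = (clique[a], clique[b])
                weights[pair] = weights.get(pair, 0) + w
    support = set(weights)
    if support != set(g.edges):
        missing = set(g.edges) - support
        extra = support - set(g.edges)
        raise ValueError(
            "clique set inconsistent with graph: "
            f"{len(missing)} uncovered edge(s), {len(extra)} non-edge pair(s)"
        )
    return CliqueGraph(g, weights)


def clique_cut(M: MaximalCliqueSet, A: Iterable[int]) -> int:
    """Clique cut of (A, Ā): each maximal clique sigma contributes
    omega(sigma) for every one of its vertex pairs split by the bipartition,
    counted once per ordered crossing pair reading, i.e. omega * |sigma∩A| *
    |sigma\\A|.  Exact integer.
    """
    Aset = set(A)
    total = 0
    for clique in M:
        k_in = sum(1 for v in clique if v in Aset)
        total += len(clique) * k_in * (len(clique) - k_in)
    return total


def clique_vol(M: MaximalCliqueSet, A: Iterable[int]) -> int:
    """Clique volume of A: the weighted volume of the induced clique graph,
    sum over v in A of the clique degree d_c(v) = sum_{sigma ∋ v}
    omega(sigma) * (omega(sigma) - 1).  This is the balancing factor the
    conductance objective divides by, and satisfies vol(A) + vol(Ā) = vol(V).
    """
    Aset = set(A)
    total = 0
    for clique in M:
        w = len(clique)
        total += w * (w - 1) * sum(1 for v in clique if v in Aset)
    return total


def membership_volume(M: MaximalCliqueSet, A: Iterable[int]) -> int:
    """Clique-size mass incident on A: sum of omega(sigma) over cliques,
    counted once per member of A in sigma.  A documentation quantity; the
    conductance objective uses :func:`clique_vol` (the weighted volume, which
    is what the cut/volume Laplacian identities hold for).
    """
    Aset = set(A)
    return sum(len(c) * sum(1 for v in c if v in Aset) for c in M)


def cut_sum(M: MaximalCliqueSet, P: Partition) -> int:
    """Unbalanced objective psi: sum of clique cuts over all parts."""
    return sum(clique_cut(M, part) for part in P.as_sets())


def _conductance(cuts, vols, total) -> float:
    phi = 0.0
    for c, v in zip(cuts, vols):
        denom = min(v, total - v)
        if denom == 0:
            if c == 0:
                raise ValueError(
                    "undefined conductance: a part has zero volume on both sides"
                )
            raise ValueError("undefined conductance: zero-volume part with cut")
        phi += c / denom
    return phi


def partition_conductance(C: CliqueGraph, P: Partition) -> float:
    """Clique conductance phi of a partition, via the weighted graph G_c:
    sum over parts of cut_c(A_i, Ā_i) / min(vol_c(A_i), vol_c(Ā_i)).

    For m = 2 both terms coincide, so phi equals twice the Cheeger ratio of
    either side.
    """
    if P.n != C.n:
        raise ValueError("partition and clique graph size mismatch")
    parts = P.as_sets()
    total = C.total_volume()
    return _conductance(
        [C.cut(p) for p in parts], [C.vol(p) for p in parts], total
    )


def partition_conductance_from_cliques(M: MaximalCliqueSet, P: Partition) -> float:
    """Clique conductance computed directly from the maximal-clique set,
    never forming W_c.  Equal to :func:`partition_conductance` by the
    cut/volume equivalence; kept as an independent route for verification.
    """
    parts = P.as_sets()
    total = clique_vol(M, range(M.n))
    return _conductance(
        [clique_cut(M, p) for p in parts], [clique_vol(M, p) for p in parts], total
    )
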