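"""Empirical verification of the bipartition performance guarantee.

For a connected binary graph, with phi* the minimum Cheeger ratio over all
proper bipartitions (the Cheeger constant of the clique graph), phi_hat the
Cheeger ratio of the sweep cut, and lambda2 the second-smallest eigenvalue
of the normalized clique-graph Laplacian, the expanded Cheeger inequality
chain reads

    2 phi* >= lambda2 >= phi_hat^2 / 2 >= phi*^2 / 2,

which implies the end-to-end guarantee  phi* <= phi_hat <= 2 sqrt(phi*).

This module provides the exhaustive optimum (exponential; capped), a random
high-dimensional geometric graph generator whose edges reflect decay of
correlation with distance, and a driver that tabulates the bound checks
over many random instances.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.spatial.distance

from .cliques import maximal_cliques
from .conductance import CliqueGraph, induced_clique_graph
from .graph import Graph, connected_components
from .spectral import sweep_bipartition

__all__ = [
    "cheeger_ratio",
    "brute_force_optimum",
    "generate_geometric_graph",
    "verify_theorem4",
    "BRUTE_FORCE_CAP",
]

#: default maximum n for exhaustive bipartition search (2^(n-1) subsets)
BRUTE_FORCE_CAP = 20

#: numerical slack for the bound checks
BOUND_TOL = 1e-8


def cheeger_ratio(C: CliqueGraph, A: Iterable[int]) -> float:
    """Cheeger ratio h(A) = cut(A, Ā) / min(vol(A), vol(Ā)) on the clique
    graph.  A must be a proper non-empty subset."""
    Aset = set(A)
    if not Aset or len(Aset) >= C.n:
        raise ValueError("A must be a proper non-empty subset of the vertices")
    cut = C.cut(Aset)
    vol = C.vol(Aset)
    denom = min(vol, C.total_volume() - vol)
    if denom == 0:
        # both sides carry cliques only if some volume exists; a zero-volume
        # side means A (or its complement) is all isolated vertices
        return 0.0 if cut == 0 else float("inf")
    return cut / denom


def brute_force_optimum(
    g: Graph, cap: int = BRUTE_FORCE_CAP, C: CliqueGraph | None = None
) -> tuple[set[int], float]:
    """Exhaustive minimum-Cheeger-ratio bipartition of the clique graph.

    Iterates the 2^(n-1) - 1 proper subsets containing vertex 0 (a subset
    and its complement have the same ratio), computing cuts and volumes in
    vectorized chunks.  Refuses n > cap because of the exponential cost.
    Returns (optimal subset A*, phi*), where phi* equals the Cheeger
    constant of the clique graph.
    """
    n = g.n
    if n < 2:
        raise ValueError("need at least 2 vertices")
    if n > cap:
        raise ValueError(
            f"n={n} exceeds the brute-force cap {cap} (2^(n-1) subsets); "
            "raise `cap` explicitly to override"
        )
    if C is None:
        C = induced_clique_graph(g, maximal_cliques(g))
    W = C.W.astype(np.float64)
    d = C.degrees.astype(np.float64)
    total = d.sum()

    best_phi = np.inf
    best_code = None
    n_codes = 1 << (n - 1)
    chunk = 1 << 16
    bits = np.arange(n)
    for start in range(0, n_codes, chunk):
        codes = np.arange(start, min(start + chunk, n_codes), dtype=np.int64)
        # vertex 0 always in A: low bit fixed to 1
        Z = ((codes[:, None] * 2 + 1) >> bits[None, :]) & 1
        Z = Z.astype(np.float64)
        full = Z.sum(axis=1) == n
        vol = Z @ d
        cut = np.einsum("ij,ij->i", Z @ W, 1.0 - Z)
        denom = np.minimum(vol, total - vol)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(denom > 0, cut / denom, np.where(cut == 0, 0.0, np.inf))
        phi[full] = np.inf  # exclude A = V
        i = int(np.argmin(phi))
        if phi[i] < best_phi:
            best_phi = float(phi[i])
            best_code = int(codes[i]) * 2 + 1
    A = {int(v) for v in range(n) if (best_code >> v) & 1}
    return A, best_phi


def generate_geometric_graph(
    n: int, rho: float, dim: int = 100, seed: int = 0
) -> Graph:
    """Random high-dimensional geometric graph.

    Each vertex gets a uniform random point in [0,1]^dim; the complete graph
    is weighted by negative Euclidean distance and binarized by keeping the
    floor(rho * n(n-1)/2) largest-weight (shortest) pairs as edges.  Ties at
    the threshold are broken by lexicographic vertex-pair order.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"rho must be in (0, 1]; got {rho}")
    rng = np.random.default_rng(seed)
    pts = rng.random((n, dim))
    dist = scipy.spatial.distance.pdist(pts)
    iu, ju = np.triu_indices(n, k=1)
    k = int(np.floor(rho * n * (n - 1) / 2))
    order = np.lexsort((ju, iu, dist))[:k]
    edges = list(zip(iu[order].tolist(), ju[order].tolist()))
    return Graph([str(i) for i in range(n)], edges)


def verify_theorem4(
    n_values: Sequence[int],
    rho: float,
    trials: int,
    seed: int,
    cap: int = BRUTE_FORCE_CAP,
    dim: int = 100,
) -> pd.DataFrame:
    """Tabulate the guarantee over random geometric graphs.

    For each n and trial: generate a graph, run the sweep cut and the
    exhaustive optimum, and record phi_hat, phi*, lambda2 along with flags
    for the Cheeger chain and the phi* <= phi_hat <= 2 sqrt(phi*) bound.
    Disconnected draws are kept (both sides of every inequality are then 0).
    """
    if max(n_values) > cap:
        raise ValueError(f"max(n_values) exceeds the brute-force cap {cap}")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        for _ in range(trials):
            sub = int(rng.integers(2**31))
            g = generate_geometric_graph(n, rho, dim=dim, seed=sub)
            connected = len(connected_components(g)) == 1
            C = induced_clique_graph(g, maximal_cliques(g))
            if connected:
                res = sweep_bipartition(C)
                phi_hat, lam = res.phi_hat, res.lambda2
                _, phi_star = brute_force_optimum(g, cap=cap, C=C)
            else:
                phi_hat = lam = phi_star = 0.0
            cheeger_ok = (
                2 * phi_star >= lam - BOUND_TOL
                and lam >= phi_hat**2 / 2 - BOUND_TOL
                and phi_hat**2 / 2 >= phi_star**2 / 2 - BOUND_TOL
            )
            theorem4_ok = (
                phi_star <= phi_hat + BOUND_TOL
                and phi_hat <= 2 * np.sqrt(phi_star) + BOUND_TOL
            )
            rows.append(
                {
                    "n": n,
                    "rho": rho,
                    "seed": sub,
                    "connected": connected,
                    "phi_star": phi_star,
                    "phi_hat": phi_hat,
                    "lambda2": lam,
                    "cheeger_ok": bool(cheeger_ok),
                    "theorem4_ok": bool(theorem4_ok),
                }
            )
    return pd.DataFrame(rows)
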