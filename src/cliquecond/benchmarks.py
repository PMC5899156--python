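"""Benchmark generators and partition scoring.

Two planted-community random-graph families are used to evaluate the
detector:

* the Girvan-Newman (GN) benchmark: 128 vertices in 4 communities of 32,
  expected degree 16, with the mixing parameter z_out giving the expected
  number of inter-community neighbours per vertex; and
* a Lancichinetti-Fortunato-Radicchi (LFR) style benchmark: power-law
  degrees (exponent gamma) and community sizes (exponent beta), mixing
  fraction mu of each vertex's edges leaving its community.

Detected partitions are scored against the planted truth with normalized
mutual information (NMI), using the arithmetic-mean-entropy normalization
I_n = MI / (H(C1)/2 + H(C2)/2), which is 1 for identical partitions and 0
for independent ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import Graph, Partition

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledBenchmark",
    "LFRParams",
    "generate_gn",
    "generate_lfr",
    "nmi",
    "benchmark_curve",
]

#: GN benchmark constants: 4 communities of 32, expected degree 16
GN_N = 128
GN_COMMUNITIES = 4
GN_SIZE = 32
GN_DEGREE = 16


@dataclass
class LabeledBenchmark:
    """A generated graph together with its planted ground-truth partition."""

    graph: Graph
    truth: Partition
    params: dict
    seed: int


@dataclass
class LFRParams:
    """Parameters of the LFR-style benchmark.

    Defaults are the standard evaluation setting: 500 vertices in 10
    communities, degrees on [20, 80] with exponent 2, community sizes on
    [30, 100] with exponent 1.1.  The bounds must satisfy k_min < s_min and
    k_max < s_max so every vertex can fit inside some community.
    """

    n: int = 500
    m_communities: int = 10
    gamma: float = 2.0
    beta: float = 1.1
    k_min: int = 20
    k_max: int = 80
    s_min: int = 30
    s_max: int = 100
    mu: float = 0.3
    max_assign_iters: int = field(default=0)  # 0 -> 10 * n

    def __post_init__(self):
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu must be in [0,1]; got {self.mu}")
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("power-law exponents must be positive")
        if not (self.k_min < self.s_min and self.k_max < self.s_max):
            raise ValueError(
                "need k_min < s_min and k_max < s_max "
                f"(got k=[{self.k_min},{self.k_max}], s=[{self.s_min},{self.s_max}])"
            )
        if not (self.m_communities * self.s_min <= self.n <= self.m_communities * self.s_max):
            raise ValueError(
                "infeasible: community-size capacity cannot sum to n "
                f"({self.m_communities} communities of [{self.s_min},{self.s_max}] vs n={self.n})"
            )
        if self.max_assign_iters == 0:
            self.max_assign_iters = 10 * self.n


# ----------------------------------------------------------------------
# Girvan-Newman benchmark


def generate_gn(z_out: float, seed: int) -> LabeledBenchmark:
    """GN benchmark graph: 128 vertices, 4 communities of 32.

    Every vertex gets exactly 16 connections, z_out of them to randomly
    chosen vertices of other communities and the rest to randomly chosen
    members of its own community.  For half-integer z_out = k + 1/2, half of
    each community's vertices get k inter-community connections and the
    other half k + 1 (general non-integer z_out is randomized per vertex
    with the matching expectation).  Stubs are paired randomly avoiding self
    and multi edges; the rare irreparable leftover stub is dropped with a
    log message.
    """
    if not (0.0 <= z_out <= GN_DEGREE):
        raise ValueError(f"z_out must be in [0, {GN_DEGREE}]; got {z_out}")
    rng = np.random.default_rng(seed)
    block = np.arange(GN_N) // GN_SIZE
    k = int(np.floor(z_out))
    frac = z_out - k
    inter = np.full(GN_N, k, dtype=np.int64)
    if frac > 0:
        # per community, a random ceil(frac * 32) of the vertices get k+1
        n_hi = int(np.round(frac * GN_SIZE))
        for c in range(GN_COMMUNITIES):
            hi = rng.choice(GN_SIZE, size=n_hi, replace=False) + c * GN_SIZE
            inter[hi] += 1
    intra = GN_DEGREE - inter

    existing: set[tuple[int, int]] = set()
    edges: list[tuple[int, int]] = []
    for c in range(GN_COMMUNITIES):
        mem = range(c * GN_SIZE, (c + 1) * GN_SIZE)
        stubs = [v for v in mem for _ in range(int(intra[v]))]
        got, left = _pair_stubs(rng, stubs, lambda u, v: False, existing)
        edges.extend(got)
        if left:
            logger.info("GN: dropped %d intra stub(s) in community %d", len(left), c)
    ext = [v for v in range(GN_N) for _ in range(int(inter[v]))]
    got, left = _pair_stubs(rng, ext, lambda u, v: block[u] == block[v], existing)
    edges.extend(got)
    if left:
        logger.info("GN: dropped %d inter stub(s)", len(left))

    g = Graph([str(i) for i in range(GN_N)], edges)
    truth = Partition(block, GN_COMMUNITIES)
    return LabeledBenchmark(g, truth, {"z_out": z_out}, seed)


# ----------------------------------------------------------------------
# LFR-style benchmark


def _truncated_power_law(rng, exponent: float, lo: int, hi: int, size: int) -> np.ndarray:
    """Discrete truncated power law P(k) ∝ k^-exponent on [lo, hi]."""
    support = np.arange(lo, hi + 1)
    p = support.astype(float) ** (-exponent)
    p /= p.sum()
    return rng.choice(support, size=size, p=p)


def _community_sizes(rng, p: LFRParams) -> np.ndarray:
    """m community sizes from the power law, nudged to sum exactly to n."""
    sizes = _truncated_power_law(rng, p.beta, p.s_min, p.s_max, p.m_communities)
    diff = p.n - int(sizes.sum())
    step = 1 if diff > 0 else -1
    guard = 0
    while diff != 0:
        i = rng.integers(p.m_communities)
        if p.s_min <= sizes[i] + step <= p.s_max:
            sizes[i] += step
            diff -= step
        guard += 1
        if guard > 100000:  # cannot happen for feasible params
            raise RuntimeError("community-size adjustment failed")
    return sizes


def _assign_communities(rng, p: LFRParams, internal: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """The homeless/kick-out assignment loop.

    All vertices start homeless; each is assigned to a random community
    whose size exceeds the vertex's internal degree, and if that community
    is already full a random member is kicked out and becomes homeless
    again.  Fails reproducibly if the loop exceeds the iteration cap.
    """
    n = p.n
    comm_of = np.full(n, -1, dtype=np.int64)
    members: list[list[int]] = [[] for _ in range(p.m_communities)]
    homeless = list(rng.permutation(n))
    iters = 0
    while homeless:
        iters += 1
        if iters > p.max_assign_iters:
            raise RuntimeError(
                f"LFR assignment loop exceeded {p.max_assign_iters} iterations "
                f"(params={p}); re-run with another seed"
            )
        v = homeless.pop()
        feasible = np.flatnonzero(sizes > internal[v])
        if len(feasible) == 0:
            raise ValueError(
                f"no community can host vertex with internal degree {internal[v]}"
            )
        c = int(rng.choice(feasible))
        if len(members[c]) >= sizes[c]:
            out = members[c].pop(int(rng.integers(len(members[c]))))
            comm_of[out] = -1
            homeless.append(out)
        members[c].append(v)
        comm_of[v] = c
    return comm_of


def _pair_stubs(rng, stubs: list[int], forbidden, existing: set, max_shuffles: int = 100):
    """Randomly pair a stub list avoiding self-pairs, duplicates, and pairs
    rejected by `forbidden`; retries by reshuffling the unmatched remainder."""
    edges: list[tuple[int, int]] = []
    remaining = list(stubs)
    for _ in range(max_shuffles):
        rng.shuffle(remaining)
        leftover: list[int] = []
        for i in range(0, len(remaining) - 1, 2):
            u, v = remaining[i], remaining[i + 1]
            e = (min(u, v), max(u, v))
            if u == v or e in existing or forbidden(u, v):
                leftover.extend((u, v))
            else:
                existing.add(e)
                edges.append(e)
        if len(remaining) % 2 == 1:
            leftover.append(remaining[-1])
        remaining = leftover
        if not remaining:
            break
    return edges, remaining


def generate_lfr(p: LFRParams, seed: int) -> LabeledBenchmark:
    """Generate one LFR-style realization.

    Degrees and community sizes are drawn from truncated power laws; the
    homeless/kick-out loop assigns vertices to communities that can host
    their internal degree; each vertex's stubs are split round-half-up into
    (1-mu)*k internal and the rest external, and stubs are paired randomly
    (internal within the community, external across communities) avoiding
    self and multi edges.  Stubs that cannot be matched after the retry cap
    are dropped with a log message, so realized degrees can fall slightly
    short of their targets at extreme mu.
    """
    rng = np.random.default_rng(seed)
    degrees = _truncated_power_law(rng, p.gamma, p.k_min, p.k_max, p.n)
    if degrees.sum() % 2 == 1:  # stub pairing needs an even total
        bump = np.flatnonzero(degrees < p.k_max)
        degrees[rng.choice(bump)] += 1
    internal = np.floor((1.0 - p.mu) * degrees + 0.5).astype(np.int64)  # round half up
    # the size draw must be able to host the largest internal degree
    for _ in range(100):
        sizes = _community_sizes(rng, p)
        if sizes.max() > internal.max():
            break
    else:
        raise ValueError(
            f"no community-size draw can host internal degree {internal.max()} "
            f"(s_max={p.s_max}); loosen the bounds"
        )
    comm_of = _assign_communities(rng, p, internal, sizes)

    members = [np.flatnonzero(comm_of == c) for c in range(p.m_communities)]
    # per-community parity fix: internal stub totals must be even; the odd
    # stub becomes external (at mu = 0 it is dropped so no cross edge appears)
    external = degrees - internal
    for c, mem in enumerate(members):
        if internal[mem].sum() % 2 == 1:
            cand = mem[internal[mem] > 0]
            v = rng.choice(cand)
            internal[v] -= 1
            if p.mu > 0:
                external[v] += 1

    existing: set[tuple[int, int]] = set()
    edges: list[tuple[int, int]] = []
    for c, mem in enumerate(members):
        stubs = [int(v) for v in mem for _ in range(int(internal[v]))]
        got, left = _pair_stubs(rng, stubs, lambda u, v: False, existing)
        edges.extend(got)
        if left:
            logger.info("LFR: dropped %d internal stub(s) in community %d", len(left), c)
    ext_stubs = [int(v) for v in range(p.n) for _ in range(int(external[v]))]
    got, left = _pair_stubs(
        rng, ext_stubs, lambda u, v: comm_of[u] == comm_of[v], existing
    )
    edges.extend(got)
    if left:
        logger.info("LFR: dropped %d external stub(s)", len(left))

    g = Graph([str(i) for i in range(p.n)], edges)
    truth = Partition(comm_of, p.m_communities)
    return LabeledBenchmark(g, truth, {"lfr": p}, seed)


# ----------------------------------------------------------------------
# Normalized mutual information


def nmi(p1: Partition, p2: Partition) -> float:
    """Normalized mutual information between two partitions of one vertex set.

    I_n = MI(C1, C2) / (H(C1)/2 + H(C2)/2) with probabilities taken as
    cluster fractions.  Symmetric, invariant to cluster relabeling, 1 for
    identical partitions, 0 for independent ones.  The 0/0 case (both
    partitions a single cluster) is defined as 1, since such partitions are
    identical.
    """
    if p1.n != p2.n:
        raise ValueError(f"partitions cover {p1.n} and {p2.n} vertices")
    # canonical argument order so symmetry holds to the last bit
    k1 = (p1.m, p1.assignment.tobytes())
    k2 = (p2.m, p2.assignment.tobytes())
    if k2 < k1:
        p1, p2 = p2, p1
    n = p1.n
    cont = np.zeros((p1.m, p2.m))
    np.add.at(cont, (p1.assignment, p2.assignment), 1.0)
    pxy = cont / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    h1 = -np.sum(px[px > 0] * np.log(px[px > 0]))
    h2 = -np.sum(py[py > 0] * np.log(py[py > 0]))
    if h1 == 0.0 and h2 == 0.0:
        logger.info("nmi: both partitions trivial; identical, returning 1")
        return 1.0
    nz = pxy > 0
    mi = np.sum(pxy[nz] * np.log(pxy[nz] / np.outer(px, py)[nz]))
    return float(max(0.0, mi) / (0.5 * h1 + 0.5 * h2))


# ----------------------------------------------------------------------
# Benchmark curves


def benchmark_curve(
    kind: str,
    grid,
    reps: int,
    m: int,
    seed: int,
    lfr_params: LFRParams | None = None,
) -> pd.DataFrame:
    """Mean/std NMI of the detector across a grid of mixing values.

    For each grid point (z_out for GN, mu for LFR), `reps` fresh
    realizations are generated, communities are detected with
    :func:`~cliquecond.spectral.detect_communities`, and NMI against the
    planted truth is averaged.  Deterministic given the seed.
    """
    from .spectral import detect_communities

    if reps < 1:
        raise ValueError("reps must be >= 1")
    if kind not in ("gn", "lfr"):
        raise ValueError(f"kind must be 'gn' or 'lfr'; got {kind!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for x in grid:
        scores = []
        for _ in range(reps):
            sub = int(rng.integers(2**31))
            if kind == "gn":
                bench = generate_gn(x, sub)
            else:
                base = lfr_params or LFRParams()
                params = LFRParams(
                    n=base.n,
                    m_communities=base.m_communities,
                    gamma=base.gamma,
                    beta=base.beta,
                    k_min=base.k_min,
                    k_max=base.k_max,
                    s_min=base.s_min,
                    s_max=base.s_max,
                    mu=float(x),
                )
                bench = generate_lfr(params, sub)
            det = detect_communities(bench.graph, m=m, seed=sub)
            scores.append(nmi(bench.truth, det.partition))
        rows.append(
            {
                "mixing": float(x),
                "mean_nmi": float(np.mean(scores)),
                "std_nmi": float(np.std(scores)),
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)
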