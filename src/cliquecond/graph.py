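"""Graph containers and I/O.

The clique-conductance method is defined on undirected, binary, loop-free
graphs.  Real network files (food webs, connectomes) are frequently directed,
weighted multigraphs, so loading is split into two stages: :func:`load_graph`
parses a file into a :class:`RawGraph` without filtering anything, and
:func:`simplify` collapses it into the :class:`Graph` the method assumes
(directed edges folded to undirected, multi-edges merged, loops deleted,
weights dropped).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "RawGraph",
    "Partition",
    "ParseError",
    "load_graph",
    "simplify",
    "connected_components",
    "write_edge_list",
    "write_partition",
    "read_partition",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass
class RawGraph:
    """A graph exactly as parsed: may contain loops, duplicates, direction."""

    labels: list[str]
    edges: list[tuple[int, int]]  # directed as written, indices into labels

    @property
    def n(self) -> int:
        return len(self.labels)


class Graph:
    """Undirected binary graph with labeled vertices.

    Vertices are indexed 0..n-1 internally; external labels round-trip
    through I/O.  Edges are stored as unordered index pairs (i < j) with no
    loops.  Binary means every edge has weight 1, which is the setting the
    clique-conductance objective is defined in; the derived clique graph is
    where weights appear.
    """

    def __init__(self, labels: Sequence[str], edges: Iterable[tuple[int, int]]):
        self.labels: list[str] = [str(x) for x in labels]
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate vertex labels")
        self.n = len(self.labels)
        es = set()
        for u, v in edges:
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u},{v}) out of range for n={self.n}")
            if u == v:
                raise ValueError(f"loop at vertex {u}; simplify first")
            es.add((min(u, v), max(u, v)))
        self.edges: frozenset[tuple[int, int]] = frozenset(es)
        self.adj: list[set[int]] = [set() for _ in range(self.n)]
        for u, v in self.edges:
            self.adj[u].add(v)
            self.adj[v].add(u)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    # -- basic queries -------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, label: str) -> int:
        return self._index[str(label)]

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def adjacency_matrix(self) -> np.ndarray:
        W = np.zeros((self.n, self.n), dtype=np.int64)
        for u, v in self.edges:
            W[u, v] = 1
            W[v, u] = 1
        return W

    def subgraph(self, vertices: Sequence[int]) -> "Graph":
        """Induced subgraph; vertex order follows `vertices`."""
        vs = list(vertices)
        pos = {v: i for i, v in enumerate(vs)}
        edges = [
            (pos[u], pos[v]) for u, v in self.edges if u in pos and v in pos
        ]
        return Graph([self.labels[v] for v in vs], edges)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Graph)
            and self.labels == other.labels
            and self.edges == other.edges
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Graph(n={self.n}, m={self.n_edges})"


@dataclass
class Partition:
    """Assignment of every vertex to exactly one of m clusters.

    Cluster ids are 0..m-1 and every cluster is non-empty, so a partition is
    a disjoint cover of the vertex set.
    """

    assignment: np.ndarray  # shape (n,), int cluster ids
    m: int = field(default=0)

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        ids = np.unique(self.assignment)
        if self.m == 0:
            self.m = len(ids)
        if not np.array_equal(ids, np.arange(self.m)):
            raise ValueError(
                f"cluster ids must be exactly 0..{self.m - 1} and non-empty; got {ids}"
            )

    @property
    def n(self) -> int:
        return len(self.assignment)

    @classmethod
    def from_sets(cls, sets: Sequence[Iterable[int]], n: int) -> "Partition":
        a = np.full(n, -1, dtype=np.int64)
        for cid, s in enumerate(sets):
            for v in s:
                if a[v] != -1:
                    raise ValueError(f"vertex {v} assigned twice")
                a[v] = cid
        if (a == -1).any():
            raise ValueError("partition does not cover all vertices")
        return cls(a, len(sets))

    def as_sets(self) -> list[set[int]]:
        out: list[set[int]] = [set() for _ in range(self.m)]
        for v, c in enumerate(self.assignment):
            out[c].add(int(v))
        return out

    def relabeled_canonical(self) -> "Partition":
        """Relabel clusters by order of first appearance (comparison aid)."""
        seen: dict[int, int] = {}
        new = np.empty_like(self.assignment)
        for i, c in enumerate(self.assignment):
            if int(c) not in seen:
                seen[int(c)] = len(seen)
            new[i] = seen[int(c)]
        return Partition(new, self.m)


# ----------------------------------------------------------------------
# Parsing


def _as_text_lines(source) -> list[str]:
    if isinstance(source, Path):
        return source.read_text().splitlines()
    if isinstance(source, str) and "\n" not in source and Path(source).exists():
        return Path(source).read_text().splitlines()
    if isinstance(source, bytes):
        return source.decode().splitlines()
    if isinstance(source, str):
        return source.splitlines()
    if isinstance(source, io.IOBase) or hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode()
        return data.splitlines()
    raise TypeError(f"cannot read graph from {type(source)!r}")


def _parse_edge_list(lines: list[str]) -> RawGraph:
    labels: list[str] = []
    index: dict[str, int] = {}
    edges: list[tuple[int, int]] = []

    def idx(lab: str) -> int:
        if lab not in index:
            index[lab] = len(labels)
            labels.append(lab)
        return index[lab]

    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) < 2:
            raise ParseError(f"line {lineno}: expected 'u v [weight]', got {line!r}")
        # optional third column (a weight) is tolerated and dropped at simplify
        edges.append((idx(parts[0]), idx(parts[1])))
    return RawGraph(labels, edges)


def _parse_gml(text: str) -> RawGraph:
    import networkx as nx

    try:
        g = nx.parse_gml(text, label=None)
    except Exception as exc:  # networkx raises several error types here
        raise ParseError(f"GML parse failed: {exc}") from exc
    nodes = list(g.nodes())
    labels = []
    for v in nodes:
        data = g.nodes[v]
        labels.append(str(data.get("label", v)))
    pos = {v: i for i, v in enumerate(nodes)}
    edges = [(pos[u], pos[v]) for u, v in g.edges()]
    return RawGraph(labels, edges)


def load_graph(source, format: str = "edge_list") -> RawGraph:
    """Parse a graph file/stream into a :class:`RawGraph` without filtering.

    Parameters
    ----------
    source:
        Path, string, bytes, or file-like object.
    format:
        ``"edge_list"`` (whitespace-separated, '#' comments, optional ignored
        weight column) or ``"gml"``.
    """
    if format == "edge_list":
        return _parse_edge_list(_as_text_lines(source))
    if format == "gml":
        return _parse_gml("\n".join(_as_text_lines(source)))
    raise ValueError(f"unknown format {format!r}; use 'edge_list' or 'gml'")


def simplify(raw: RawGraph) -> Graph:
    """Collapse a raw graph into the undirected binary loop-free form.

    Directed edge pairs (u,v),(v,u) merge into one undirected edge,
    multi-edges are deduplicated, loops are deleted, and any input weights
    are discarded (all retained edges have weight 1).
    """
    if raw.n == 0:
        raise ValueError("empty vertex set")
    edges = {(min(u, v), max(u, v)) for u, v in raw.edges if u != v}
    n_loops = sum(1 for u, v in raw.edges if u == v)
    if n_loops:
        logger.info("simplify: removed %d loop(s)", n_loops)
    return Graph(raw.labels, edges)


def connected_components(g: Graph) -> list[set[int]]:
    """Connected components as vertex-index sets (BFS)."""
    seen = np.zeros(g.n, dtype=bool)
    comps: list[set[int]] = []
    for s in range(g.n):
        if seen[s]:
            continue
        comp = {s}
        seen[s] = True
        stack = [s]
        while stack:
            u = stack.pop()
            for v in g.adj[u]:
                if not seen[v]:
                    seen[v] = True
                    comp.add(v)
                    stack.append(v)
        comps.append(comp)
    return comps


# ----------------------------------------------------------------------
# Writing


def write_edge_list(g: Graph, path) -> None:
    with open(path, "w") as f:
        for u, v in sorted(g.edges):
            f.write(f"{g.labels[u]}\t{g.labels[v]}\n")


def write_partition(g: Graph, p: Partition, path, header: str | None = None) -> None:
    """Write `label <TAB> cluster-id`, one vertex per line."""
    with open(path, "w") as f:
        if header:
            f.write(f"# {header}\n")
        for v in range(g.n):
            f.write(f"{g.labels[v]}\t{int(p.assignment[v])}\n")


def read_partition(source, g: Graph) -> Partition:
    """Read a two-column label/cluster TSV aligned to graph `g`."""
    a = np.full(g.n, -1, dtype=np.int64)
    ids: dict[str, int] = {}
    for lineno, line in enumerate(_as_text_lines(source), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected 'label cluster', got {line!r}")
        lab, cid = parts
        if cid not in ids:
            ids[cid] = len(ids)
        try:
            a[g.index_of(lab)] = ids[cid]
        except KeyError:
            raise ParseError(f"line {lineno}: unknown vertex label {lab!r}")
    if (a == -1).any():
        missing = [g.labels[i] for i in np.flatnonzero(a == -1)[:5]]
        raise ParseError(f"partition does not cover vertices {missing}")
    return Partition(a, len(ids))
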