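"""Bundled toy fixtures.

Ships three tiny networks used throughout the documentation and tests:

* the Zachary karate club (34 members, 78 friendship ties, public-domain
  classic), with the two recorded post-fission factions;
* two triangles joined by a bridge edge (the smallest graph with an
  interesting sweep cut, optimal conductance 0.1);
* the complete tripartite graph K(3,3,3), which attains the 3^(n/3)
  maximal-clique bound (27 cliques on 9 vertices).
"""

from __future__ import annotations

from importlib import resources

from .graph import Graph, Partition, load_graph, read_partition, simplify

__all__ = ["karate_club", "karate_factions", "bridge_of_triangles", "k333", "data_path"]


def data_path(name: str):
    """Filesystem path of a bundled data file (context-manager free for
    editable installs; files ship inside the package)."""
    return resources.files("cliquecond.data") / name


def _load(name: str) -> Graph:
    return simplify(load_graph(data_path(name).read_text(), format="edge_list"))


def karate_club() -> Graph:
    """Zachary's karate club friendship network (labels "1".."34")."""
    return _load("karate.edgelist")


def karate_factions(g: Graph | None = None) -> Partition:
    """The two factions recorded after the club's fission
    (cluster 0 = instructor's side, cluster 1 = president's side)."""
    g = g or karate_club()
    return read_partition(data_path("karate_factions.tsv").read_text(), g)


def bridge_of_triangles() -> Graph:
    """Two triangles {1,2,3}, {4,5,6} joined by the edge 3-4."""
    return _load("bridge_triangles.edgelist")


def k333() -> Graph:
    """Complete tripartite K(3,3,3): 27 maximal 3-cliques (Moon-Moser)."""
    return _load("k333.edgelist")
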