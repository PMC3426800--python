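"""Breadth-first nearest-neighbor graph construction around a seed concept.

Starting from a seed CUI, each frontier concept queries its top-k
cosine neighbors in the semantic vector store; previously unseen
neighbors join the graph one level deeper, connected by an edge whose
weight is the cosine at build time. With branching b and depth d the
graph holds at most 1 + b + b^2 + ... + b^d nodes (259 for the default
b=6, d=3, mirroring working-memory-sized expansion). A concept already
present is not added again and, by default, contributes no new edge,
which keeps the construction near-tree; the ``cross_edges`` flag adds
edges between already-present pairs instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Tuple

import networkx as nx

from .errors import ParameterError
from .rri import SemanticVectorStore, nearest_neighbors
from .types import Source

__all__ = [
    "ConceptGraph",
    "build_bfs_graph",
    "graph_stats",
    "GraphStats",
    "level_capacity",
    "max_node_count",
]


@dataclass
class ConceptGraph:
    """A weighted, optionally relation-labeled concept graph with a seed.

    Wraps an undirected :class:`networkx.Graph`; every node carries a
    ``depth`` attribute (BFS level from the seed at build time), every
    edge a ``weight`` (cosine), plus ``relation_label``/``source`` once
    the knowledge filter has run.
    """

    seed: str
    g: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        if self.seed not in self.g:
            self.g.add_node(self.seed, depth=0)
        if any(u == v for u, v in self.g.edges):
            raise ParameterError("self-loops are not allowed")

    @property
    def nodes(self) -> List[str]:
        return list(self.g.nodes)

    def depth_of(self, cui: str) -> int:
        return int(self.g.nodes[cui]["depth"])

    def edge_data(self, u: str, v: str) -> dict:
        return self.g.edges[u, v]

    def copy(self) -> "ConceptGraph":
        return ConceptGraph(seed=self.seed, g=self.g.copy())

    def _canonical(self):
        nodes = {n: int(d["depth"]) for n, d in self.g.nodes(data=True)}
        edges = {
            frozenset((u, v)): (
                float(d["weight"]),
                d.get("relation_label"),
                d.get("source"),
            )
            for u, v, d in self.g.edges(data=True)
        }
        return self.seed, nodes, edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConceptGraph):
            return NotImplemented
        return self._canonical() == other._canonical()


def level_capacity(branching: int, level: int) -> int:
    """Maximum number of concepts a BFS level can add (b^level)."""
    return branching ** level


def max_node_count(branching: int, max_depth: int) -> int:
    """Upper bound on total node count: 1 + b + b^2 + ... + b^d."""
    return sum(branching ** level for level in range(max_depth + 1))


def build_bfs_graph(
    store: SemanticVectorStore,
    seed: str,
    branching: int = 6,
    max_depth: int = 3,
    min_cosine: float = 0.0,
    cross_edges: bool = False,
) -> ConceptGraph:
    """Grow the capped breadth-first nearest-neighbor graph from ``seed``.

    Frontier nodes are processed in insertion order; each queries its
    top-``branching`` neighbors (ties by ascending CUI) and keeps those
    with cosine >= ``min_cosine``. New neighbors join one level deeper
    with an edge weighted by the cosine; already-present neighbors are
    skipped (or, with ``cross_edges``, linked without being re-added).
    """
    if seed not in store:
        raise KeyError(f"seed {seed!r} not in vector store")
    if branching < 1:
        raise ParameterError(f"branching must be >= 1, got {branching}")
    if max_depth < 0:
        raise ParameterError(f"max_depth must be >= 0, got {max_depth}")

    g = nx.Graph()
    g.add_node(seed, depth=0)
    frontier: List[str] = [seed]
    for depth in range(1, max_depth + 1):
        next_frontier: List[str] = []
        for u in frontier:
            for v, cos in nearest_neighbors(store, u, branching):
                if cos < min_cosine:
                    break  # results are sorted descending
                if v in g:
                    if cross_edges and not g.has_edge(u, v):
                        g.add_edge(u, v, weight=cos, relation_label=None, source=None)
                    continue
                g.add_node(v, depth=depth)
                g.add_edge(u, v, weight=cos, relation_label=None, source=None)
                next_frontier.append(v)
        frontier = next_frontier
    return ConceptGraph(seed=seed, g=g)


class GraphStats(NamedTuple):
    node_count: int
    edge_count: int
    seed_component_node_count: int
    seed_component_edge_count: int


def graph_stats(graph: ConceptGraph) -> GraphStats:
    """Node/edge counts for the whole graph and for the seed's connected
    component (the only part that can influence the seed readout)."""
    comp = nx.node_connected_component(graph.g, graph.seed)
    sub = graph.g.subgraph(comp)
    return GraphStats(
        node_count=graph.g.number_of_nodes(),
        edge_count=graph.g.number_of_edges(),
        seed_component_node_count=sub.number_of_nodes(),
        seed_component_edge_count=sub.number_of_edges(),
    )
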