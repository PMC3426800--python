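"""Shared fixtures: hand-built corpora, the published graph topology, and
small simulated cohorts. All fixtures are generated programmatically."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from phenospread import (
    ConceptCorpus,
    ConceptGraph,
    ConceptMention,
    KnowledgeBase,
    PatientDocument,
    RelationTriple,
    Source,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_corpus(
    docs: Sequence[Tuple[str, str, Sequence[Tuple[str, int]]]]
) -> ConceptCorpus:
    """Build a corpus from (patient_id, doc_id, [(cui, confidence), ...]) rows."""
    return ConceptCorpus(
        [
            PatientDocument(pid, did, tuple(ConceptMention(c, s) for c, s in mentions))
            for pid, did, mentions in docs
        ]
    )


@pytest.fixture
def tiny_corpus() -> ConceptCorpus:
    """Three documents over two patients; duplicates preserved."""
    return make_corpus(
        [
            ("p1", "d1", [("C0006142", 1000), ("C0000001", 600), ("C0000001", 400)]),
            ("p1", "d2", [("C0000002", 800)]),
            ("p2", "d1", [("C0006142", 900), ("C0000002", 700)]),
        ]
    )


def build_graph_fixture(
    seed: str,
    nodes: Sequence[Tuple[str, int]],
    edges: Sequence[Tuple[str, str, float]],
) -> ConceptGraph:
    g = nx.Graph()
    for cui, depth in nodes:
        g.add_node(cui, depth=depth)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, relation_label=None, source=None)
    return ConceptGraph(seed=seed, g=g)


@pytest.fixture
def paper_topology() -> Tuple[ConceptGraph, KnowledgeBase]:
    """A 20-node/18-edge graph whose knowledge-supported part is the published
    topology: a 14-node/14-edge seed component, with a 6-node piece that the
    filter disconnects entirely.

    The fixture graph itself already has the 6-node/4-edge piece detached
    (20 nodes, 18 edges); the KB supports exactly the 14 seed-component
    edges, so filtering leaves (20 nodes, 14 edges) and the active subgraph
    is (14 nodes, 14 edges).
    """
    seed = "C0006142"
    a = [f"C10000{i:02d}" for i in range(1, 14)]  # 13 companions of the seed
    b = [f"C20000{i:02d}" for i in range(1, 7)]  # detached piece
    nodes = [(seed, 0)] + [(c, 1 + i // 6) for i, c in enumerate(a)] + [(c, 3) for c in b]
    # seed component: star over the first 6 + chains; 13 tree edges + 1 extra = 14
    tree = [(seed, a[i], 0.9 - 0.01 * i) for i in range(6)]
    tree += [(a[0], a[6], 0.5), (a[1], a[7], 0.5), (a[2], a[8], 0.45), (a[3], a[9], 0.44)]
    tree += [(a[6], a[10], 0.4), (a[7], a[11], 0.38), (a[8], a[12], 0.35)]
    extra = [(a[4], a[5], 0.3)]  # closes one cycle: 14 edges on 14 nodes
    piece = [(b[0], b[1], 0.2), (b[1], b[2], 0.2), (b[2], b[3], 0.19), (b[3], b[4], 0.18)]
    graph = build_graph_fixture(seed, nodes, tree + extra + piece)
    kb = KnowledgeBase(
        RelationTriple(u, "ASSOCIATED_WITH", v, Source.LITERATURE)
        for u, v, _ in tree + extra
    )
    return graph, kb
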