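"""Knowledge-based curation of the nearest-neighbor graph.

Cosine similarity measures general distributional relatedness only; it
says nothing about the *nature* of a relationship, so nearest-neighbor
graphs are noisy. Each candidate edge is therefore checked against two
relation databases — a curated thesaurus (UMLS Metathesaurus relations)
and literature predications (SemRep triples). Any relation between the
two endpoint concepts, in either direction and of any predicate type,
validates the edge; unsupported edges are deleted. Surviving edges are
labeled with the supporting predicate, thesaurus labels rendered with a
"UMLS:" prefix and literature labels bare. Nodes orphaned by filtering
are kept (they simply cannot influence the seed readout);
``active_subgraph`` restricts to the seed's connected component for
inference.
"""

from __future__ import annotations

import logging
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import networkx as nx

from .errors import ParameterError
from .graph import ConceptGraph
from .types import RelationTriple, Source

logger = logging.getLogger(__name__)

__all__ = ["KnowledgeBase", "validate_edge", "filter_graph", "active_subgraph"]


class KnowledgeBase:
    """A de-duplicated triple set with symmetric unordered-pair lookup.

    Self-relations (subject == object) are stored but ignored by
    lookups; a self-loop cannot validate a graph edge.
    """

    def __init__(self, triples: Iterable[RelationTriple]) -> None:
        self.triples: FrozenSet[RelationTriple] = frozenset(triples)
        self._index: Dict[FrozenSet[str], List[Tuple[str, Source]]] = {}
        for t in sorted(self.triples, key=lambda t: (t.subject, t.predicate, t.object, t.source.value)):
            if t.subject == t.object:
                continue
            self._index.setdefault(frozenset((t.subject, t.object)), []).append(
                (t.predicate, t.source)
            )

    def lookup(self, u: str, v: str) -> List[Tuple[str, Source]]:
        """All (predicate, source) pairs relating u and v, in either direction."""
        return list(self._index.get(frozenset((u, v)), ()))

    def __len__(self) -> int:
        return len(self.triples)


def validate_edge(kb: KnowledgeBase, u: str, v: str) -> Optional[Tuple[str, Source]]:
    """The supporting relation for the pair (u, v), or ``None``.

    Thesaurus relations take precedence over literature relations; within
    a source the lexicographically smallest predicate wins (a
    deterministic convention — the databases impose no tie rule).
    Thesaurus labels are returned as "UMLS:<predicate>", literature
    labels bare.
    """
    if u == v:
        raise ParameterError(f"cannot validate a self-edge on {u!r}")
    entries = kb.lookup(u, v)
    if not entries:
        return None
    thesaurus = sorted(p for p, s in entries if s is Source.THESAURUS)
    if thesaurus:
        return f"UMLS:{thesaurus[0]}", Source.THESAURUS
    literature = sorted(p for p, s in entries if s is Source.LITERATURE)
    return literature[0], Source.LITERATURE


def filter_graph(graph: ConceptGraph, kb: KnowledgeBase) -> ConceptGraph:
    """Remove edges unsupported by both databases; label the survivors.

    Nodes are preserved even when every incident edge is deleted, and
    edge weights are untouched. Idempotent: filtering a filtered graph
    changes nothing.
    """
    out = graph.copy()
    for u, v in list(out.g.edges):
        support = validate_edge(kb, u, v)
        if support is None:
            logger.debug("edge %s -- %s removed (no supporting relation)", u, v)
            out.g.remove_edge(u, v)
        else:
            label, source = support
            out.g.edges[u, v]["relation_label"] = label
            out.g.edges[u, v]["source"] = source
            logger.debug("edge %s -- %s kept (%s, %s)", u, v, label, source.value)
    return out


def active_subgraph(graph: ConceptGraph) -> ConceptGraph:
    """Restriction to the connected component containing the seed — the only
    nodes whose activation can reach the seed readout."""
    comp = nx.node_connected_component(graph.g, graph.seed)
    return ConceptGraph(seed=graph.seed, g=graph.g.subgraph(comp).copy())
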