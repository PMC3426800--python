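"""Readers and writers for all on-disk artifacts.

Every tabular artifact is a UTF-8, LF-terminated, tab-separated file
with a mandatory header row. These are deliberately minimal normalized
interchange formats: native MetaMap machine output, UMLS RRF files and
SemMedDB dumps vary by version and are out of scope; converters can
target these TSVs.

Formats
-------
corpus.tsv        patient_id, doc_id, cui, confidence   (one row per mention instance)
kb.tsv            subject, predicate, object, source    (source in {THESAURUS, LITERATURE})
labels.tsv        patient_id, label                     (label in {0, 1})
predictions.tsv   patient_id, seed_activation, label    (sorted by patient_id)
graph TSV         edge list cui_u, cui_v, weight, relation_label, source,
                  preceded by '# seed' and '# node' comment lines carrying
                  the seed CUI and every node with its BFS depth (so that
                  isolated nodes and depths survive a round trip)
graph GraphML     same attributes via networkx
vector store      cui followed by dim floats (9 significant digits), with a
                  sidecar '<path>.meta' key=value file (dim, nonzeros,
                  master_seed, corpus_checksum)
config            flat key=value lines, '#' comments
"""

from __future__ import annotations

import csv
import hashlib
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, TextIO, Tuple

import networkx as nx
import numpy as np

from .errors import ParseError, ValidationError
from .types import (
    ConceptCorpus,
    ConceptMention,
    GoldLabels,
    PatientDocument,
    PredictionResult,
    RelationTriple,
    Source,
)

__all__ = [
    "read_concept_corpus",
    "write_concept_corpus",
    "read_knowledge_base",
    "write_knowledge_base",
    "read_graph",
    "write_graph",
    "read_gold_labels",
    "write_gold_labels",
    "read_predictions",
    "write_predictions",
    "read_vector_store",
    "write_vector_store",
    "read_config",
    "write_config",
    "sha256_of",
    "atomic_write",
]

_CORPUS_HEADER = ["patient_id", "doc_id", "cui", "confidence"]
_KB_HEADER = ["subject", "predicate", "object", "source"]
_LABELS_HEADER = ["patient_id", "label"]
_PRED_HEADER = ["patient_id", "seed_activation", "label"]
_GRAPH_HEADER = ["cui_u", "cui_v", "weight", "relation_label", "source"]


@contextmanager
def atomic_write(path: os.PathLike | str) -> Iterator[TextIO]:
    """Write to a temporary file and rename into place on success.

    A failed stage never leaves a partially written artifact behind.
    """
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def sha256_of(path: os.PathLike | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_tsv(path: os.PathLike | str, header: Sequence[str]) -> Iterator[Tuple[int, List[str]]]:
    """Yield (line_number, row) after checking the header; skip blank lines."""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            first = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: missing header (expected {list(header)})") from None
        if first != list(header):
            raise ParseError(f"{path}: bad header {first!r}, expected {list(header)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            yield lineno, row


# ---------------------------------------------------------------------------
# concept corpus

def read_concept_corpus(path: os.PathLike | str) -> ConceptCorpus:
    """Read a corpus TSV; duplicate mentions are preserved, rows grouped by
    (patient_id, doc_id) in first-appearance order."""
    groups: Dict[Tuple[str, str], List[ConceptMention]] = {}
    n_rows = 0
    for lineno, (pid, did, cui, conf) in ((ln, r) for ln, r in _read_tsv(path, _CORPUS_HEADER)):
        try:
            confidence = int(conf)
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-integer confidence {conf!r}") from None
        try:
            mention = ConceptMention(cui=cui, confidence=confidence)
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
        groups.setdefault((pid, did), []).append(mention)
        n_rows += 1
    if n_rows == 0:
        raise ParseError(f"{path}: empty corpus (no data rows)")
    docs = [
        PatientDocument(patient_id=pid, doc_id=did, mentions=tuple(ms))
        for (pid, did), ms in groups.items()
    ]
    return ConceptCorpus(docs)


def write_concept_corpus(corpus: ConceptCorpus, path: os.PathLike | str) -> None:
    with atomic_write(path) as fh:
        fh.write("\t".join(_CORPUS_HEADER) + "\n")
        for doc in corpus:
            for m in doc.mentions:
                fh.write(f"{doc.patient_id}\t{doc.doc_id}\t{m.cui}\t{m.confidence}\n")


# ---------------------------------------------------------------------------
# knowledge base

def read_knowledge_base(path: os.PathLike | str) -> Set[RelationTriple]:
    """Read a relation-triple TSV into a de-duplicated set."""
    triples: Set[RelationTriple] = set()
    for lineno, (s, p, o, src) in _read_tsv(path, _KB_HEADER):
        try:
            source = Source(src)
        except ValueError:
            raise ValidationError(
                f"{path}: line {lineno}: unknown source {src!r} "
                f"(expected THESAURUS or LITERATURE)"
            ) from None
        try:
            triples.add(RelationTriple(subject=s, predicate=p, object=o, source=source))
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return triples


def write_knowledge_base(triples: Iterable[RelationTriple], path: os.PathLike | str) -> None:
    rows = sorted(
        (t.subject, t.predicate, t.object, t.source.value) for t in triples
    )
    with atomic_write(path) as fh:
        fh.write("\t".join(_KB_HEADER) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# gold labels / predictions

def read_gold_labels(path: os.PathLike | str) -> GoldLabels:
    labels: GoldLabels = {}
    for lineno, (pid, lab) in _read_tsv(path, _LABELS_HEADER):
        if pid in labels:
            raise ValidationError(f"{path}: line {lineno}: duplicate patient_id {pid!r}")
        if lab not in ("0", "1"):
            raise ValidationError(f"{path}: line {lineno}: label {lab!r} not in {{0, 1}}")
        labels[pid] = lab == "1"
    return labels


def write_gold_labels(labels: GoldLabels, path: os.PathLike | str) -> None:
    with atomic_write(path) as fh:
        fh.write("\t".join(_LABELS_HEADER) + "\n")
        for pid in sorted(labels):
            fh.write(f"{pid}\t{int(labels[pid])}\n")


def read_predictions(path: os.PathLike | str, method: str = "GRAPH") -> List[PredictionResult]:
    out: List[PredictionResult] = []
    seen: Set[str] = set()
    for lineno, (pid, act, lab) in _read_tsv(path, _PRED_HEADER):
        if pid in seen:
            raise ValidationError(f"{path}: line {lineno}: duplicate patient_id {pid!r}")
        if lab not in ("0", "1"):
            raise ValidationError(f"{path}: line {lineno}: label {lab!r} not in {{0, 1}}")
        try:
            activation = float(act)
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: bad activation {act!r}") from None
        seen.add(pid)
        out.append(PredictionResult(pid, activation, lab == "1", method))
    return out


def write_predictions(results: Iterable[PredictionResult], path: os.PathLike | str) -> None:
    """Write predictions sorted by patient_id (deterministic diff-friendly order)."""
    rows = sorted(results, key=lambda r: r.patient_id)
    with atomic_write(path) as fh:
        fh.write("\t".join(_PRED_HEADER) + "\n")
        for r in rows:
            fh.write(f"{r.patient_id}\t{r.seed_activation!r}\t{int(r.label)}\n")


# ---------------------------------------------------------------------------
# graphs

def write_graph(graph, path: os.PathLike | str, format: str = "TSV_EDGELIST") -> None:
    """Write a ConceptGraph as a TSV edge list or as GraphML.

    TSV: nodes (with BFS depth) and the seed ride in '#' comment lines so the
    body stays a plain edge list; floats use repr so a round trip is
    bit-exact. GraphML carries the same attributes via networkx.
    """
    fmt = format.upper()
    if fmt == "TSV_EDGELIST":
        with atomic_write(path) as fh:
            fh.write(f"# seed\t{graph.seed}\n")
            for cui in sorted(graph.g.nodes):
                fh.write(f"# node\t{cui}\t{graph.g.nodes[cui]['depth']}\n")
            fh.write("\t".join(_GRAPH_HEADER) + "\n")
            for u, v, data in sorted(graph.g.edges(data=True)):
                label = data.get("relation_label") or ""
                source = data["source"].value if data.get("source") else ""
                fh.write(f"{u}\t{v}\t{data['weight']!r}\t{label}\t{source}\n")
    elif fmt == "GRAPHML":
        g = nx.Graph(seed=graph.seed)
        for cui in graph.g.nodes:
            g.add_node(cui, depth=int(graph.g.nodes[cui]["depth"]))
        for u, v, data in graph.g.edges(data=True):
            attrs = {"weight": float(data["weight"])}
            if data.get("relation_label"):
                attrs["relation_label"] = data["relation_label"]
            if data.get("source"):
                attrs["source"] = data["source"].value
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, str(path))
    else:
        raise ValidationError(f"unknown graph format {format!r}")


def read_graph(path: os.PathLike | str, format: str = "TSV_EDGELIST"):
    from .graph import ConceptGraph  # local import to avoid a cycle

    fmt = format.upper()
    if fmt == "GRAPHML":
        g = nx.read_graphml(str(path))
        seed = g.graph.get("seed")
        if seed is None:
            raise ParseError(f"{path}: GraphML missing graph attribute 'seed'")
        out = nx.Graph()
        for cui, data in g.nodes(data=True):
            out.add_node(cui, depth=int(data["depth"]))
        for u, v, data in g.edges(data=True):
            out.add_edge(
                u,
                v,
                weight=float(data["weight"]),
                relation_label=data.get("relation_label"),
                source=Source(data["source"]) if data.get("source") else None,
            )
        return ConceptGraph(seed=seed, g=out)
    if fmt != "TSV_EDGELIST":
        raise ValidationError(f"unknown graph format {format!r}")

    seed: Optional[str] = None
    g = nx.Graph()
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "seed" and len(parts) == 2:
                    seed = parts[1]
                elif parts[0] == "node" and len(parts) == 3:
                    g.add_node(parts[1], depth=int(parts[2]))
                else:
                    raise ParseError(f"{path}: line {lineno}: bad comment record {line!r}")
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != _GRAPH_HEADER:
                    raise ParseError(f"{path}: line {lineno}: bad header {fields!r}")
                header_seen = True
                continue
            if len(fields) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 fields, got {len(fields)}")
            u, v, w, label, source = fields
            g.add_edge(
                u,
                v,
                weight=float(w),
                relation_label=label or None,
                source=Source(source) if source else None,
            )
    if seed is None:
        raise ParseError(f"{path}: missing '# seed' record")
    if not header_seen:
        raise ParseError(f"{path}: missing edge-list header")
    return ConceptGraph(seed=seed, g=g)


# ---------------------------------------------------------------------------
# vector stores

def write_vector_store(store, path: os.PathLike | str, metadata: Optional[Dict[str, str]] = None) -> None:
    """Persist a semantic vector store as TSV (cui + floats, 9 significant
    digits) with a '<path>.meta' sidecar of key=value metadata."""
    with atomic_write(path) as fh:
        fh.write("cui\tvector\n")
        for cui in store.cuis():
            vec = " ".join(f"{x:.9g}" for x in store.vector(cui))
            fh.write(f"{cui}\t{vec}\n")
    meta = {"dim": str(store.dim)}
    if metadata:
        meta.update({k: str(v) for k, v in metadata.items()})
    write_config(meta, str(path) + ".meta")


def read_vector_store(path: os.PathLike | str):
    from .rri import SemanticVectorStore  # local import to avoid a cycle

    vectors: Dict[str, np.ndarray] = {}
    dim: Optional[int] = None
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != "cui\tvector":
            raise ParseError(f"{path}: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                cui, rest = line.split("\t", 1)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields") from None
            vec = np.array(rest.split(), dtype=float)
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ParseError(f"{path}: line {lineno}: inconsistent vector length")
            vectors[cui] = vec
    if not vectors:
        raise ParseError(f"{path}: empty vector store")
    return SemanticVectorStore(vectors)


# ---------------------------------------------------------------------------
# flat config

def read_config(path: os.PathLike | str) -> Dict[str, str]:
    """Read a flat key=value config file ('#' starts a comment line)."""
    out: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}: line {lineno}: expected key=value, got {line!r}")
            key, value = line.split("=", 1)
            key = key.strip()
            if key in out:
                raise ValidationError(f"{path}: line {lineno}: duplicate key {key!r}")
            out[key] = value.strip()
    return out


def write_config(config: Dict[str, str], path: os.PathLike | str) -> None:
    with atomic_write(path) as fh:
        for key in sorted(config):
            fh.write(f"{key}={config[key]}\n")
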