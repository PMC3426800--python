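"""Reflective random indexing (RRI) of clinical concepts.

Random indexing sidesteps the dimensionality of the concept vocabulary
(the UMLS has millions of CUIs) by assigning every concept a random
sparse *elemental* vector in a fixed low-dimensional space; such vectors
are mutually near-orthogonal with high probability. A *document* vector
is the log-entropy-weighted superposition of the elemental vectors of
the concepts it mentions, normalized to unit length. The reflective
step then builds a *semantic* vector per concept by summing the
document vectors of every document the concept occurs in and
normalizing. Because two concepts that never co-occur can still share
containing-document neighborhoods, cosine similarity between semantic
vectors captures second-order (indirect) association — the property the
downstream graph construction relies on.

One reflective iteration (elemental -> document -> concept) is
performed; weighting follows the standard LSA log-entropy scheme with
local weight log(1 + tf) (natural log) and global entropy weight

    g_i = 1 + sum_j p_ij * log(p_ij) / log(n),   p_ij = tf_ij / gf_i

over the n documents of the corpus, so g = 1 for a concept confined to
a single document and g -> 0 for a concept spread uniformly over all.
"""

from __future__ import annotations

import hashlib
import logging
import math
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .errors import ParameterError
from .types import ConceptCorpus

logger = logging.getLogger(__name__)

DEFAULT_DIM = 1000
DEFAULT_NONZEROS = 10

__all__ = [
    "DEFAULT_DIM",
    "DEFAULT_NONZEROS",
    "make_elemental_vector",
    "ElementalVectorStore",
    "log_entropy_weights",
    "DocumentVectorStore",
    "build_document_vectors",
    "SemanticVectorStore",
    "build_concept_vectors",
    "build_semantic_vectors",
    "cosine",
    "nearest_neighbors",
]


def _rng_for(master_seed: int, cui: str) -> np.random.Generator:
    # Counter-based keying: the vector for a CUI depends only on
    # (master_seed, cui), never on generation order.
    digest = hashlib.sha256(f"{master_seed}\x00{cui}".encode("utf-8")).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def make_elemental_vector(
    cui: str,
    dim: int = DEFAULT_DIM,
    nonzeros: int = DEFAULT_NONZEROS,
    master_seed: int = 0,
) -> np.ndarray:
    """Deterministic sparse ternary elemental vector for one CUI.

    Exactly ``nonzeros/2`` entries are +1 and ``nonzeros/2`` are -1, at
    positions drawn without replacement by a generator keyed on
    ``(master_seed, cui)``; all other entries are 0.
    """
    if nonzeros <= 0 or nonzeros % 2 != 0:
        raise ParameterError(f"nonzeros must be a positive even integer, got {nonzeros}")
    if nonzeros > dim:
        raise ParameterError(f"nonzeros ({nonzeros}) must not exceed dim ({dim})")
    rng = _rng_for(master_seed, cui)
    positions = rng.choice(dim, size=nonzeros, replace=False)
    vec = np.zeros(dim)
    vec[positions[: nonzeros // 2]] = 1.0
    vec[positions[nonzeros // 2 :]] = -1.0
    return vec


class ElementalVectorStore:
    """Lazy, deterministic store of elemental vectors keyed on (master_seed, cui)."""

    def __init__(
        self,
        dim: int = DEFAULT_DIM,
        nonzeros: int = DEFAULT_NONZEROS,
        master_seed: int = 0,
    ) -> None:
        if nonzeros <= 0 or nonzeros % 2 != 0 or nonzeros > dim:
            raise ParameterError(
                f"nonzeros must be a positive even integer <= dim, got {nonzeros} (dim={dim})"
            )
        self.dim = dim
        self.nonzeros = nonzeros
        self.master_seed = master_seed
        self._cache: Dict[str, np.ndarray] = {}

    def vector(self, cui: str) -> np.ndarray:
        vec = self._cache.get(cui)
        if vec is None:
            vec = make_elemental_vector(cui, self.dim, self.nonzeros, self.master_seed)
            self._cache[cui] = vec
        return vec

    def __contains__(self, cui: str) -> bool:  # every CUI has a vector by construction
        return True


def log_entropy_weights(corpus: ConceptCorpus) -> Dict[str, float]:
    """Global entropy weight g in [0, 1] for every CUI in the corpus.

    With tf_ij the count of CUI i in document j, gf_i = sum_j tf_ij and
    n the number of documents: g_i = 1 + sum_j p_ij log(p_ij) / log(n).
    For a single-document corpus g_i = 1 by convention.
    """
    n = len(corpus)
    tf: Dict[str, Dict[int, int]] = {}
    for j, doc in enumerate(corpus):
        for m in doc.mentions:
            tf.setdefault(m.cui, {}).setdefault(j, 0)
            tf[m.cui][j] += 1
    weights: Dict[str, float] = {}
    log_n = math.log(n) if n > 1 else None
    for cui, counts in tf.items():
        if log_n is None:
            weights[cui] = 1.0
            continue
        gf = sum(counts.values())
        entropy = sum((c / gf) * math.log(c / gf) for c in counts.values())
        g = 1.0 + entropy / log_n
        # clamp rounding noise into the mathematical range; a uniformly
        # spread concept must weigh exactly zero
        if g < 1e-12:
            g = 0.0
        weights[cui] = min(1.0, g)
    return weights


class DocumentVectorStore:
    """Unit document vectors keyed by (patient_id, doc_id); zero vectors mark
    documents whose every concept had zero global weight."""

    def __init__(self, vectors: Mapping[Tuple[str, str], np.ndarray], dim: int) -> None:
        self._vectors = dict(vectors)
        self.dim = dim

    def vector(self, patient_id: str, doc_id: str) -> np.ndarray:
        try:
            return self._vectors[(patient_id, doc_id)]
        except KeyError:
            raise KeyError(f"unknown document ({patient_id!r}, {doc_id!r})") from None

    def keys(self) -> List[Tuple[str, str]]:
        return list(self._vectors)

    def __len__(self) -> int:
        return len(self._vectors)


def build_document_vectors(
    corpus: ConceptCorpus,
    elemental: ElementalVectorStore,
    weights: Mapping[str, float],
) -> DocumentVectorStore:
    """Superpose weighted elemental vectors per document and normalize.

    Raw vector = sum over distinct CUIs i in the document of
    log(1 + tf_ij) * g_i * elemental(i); scaled to unit norm. A raw
    all-zero vector (every concept fully de-weighted) is kept as the
    zero vector with a warning, so degenerate documents do not abort a
    corpus-scale run.
    """
    vectors: Dict[Tuple[str, str], np.ndarray] = {}
    for doc in corpus:
        tf: Dict[str, int] = {}
        for m in doc.mentions:
            tf[m.cui] = tf.get(m.cui, 0) + 1
        raw = np.zeros(elemental.dim)
        for cui, count in tf.items():
            g = weights[cui]
            if g == 0.0:
                continue
            raw += math.log1p(count) * g * elemental.vector(cui)
        norm = float(np.linalg.norm(raw))
        if norm == 0.0:
            logger.warning(
                "document (%s, %s) has zero vector (all concepts de-weighted)",
                doc.patient_id,
                doc.doc_id,
            )
            vectors[(doc.patient_id, doc.doc_id)] = raw
        else:
            vectors[(doc.patient_id, doc.doc_id)] = raw / norm
    return DocumentVectorStore(vectors, elemental.dim)


class SemanticVectorStore:
    """Unit semantic vectors per CUI with cosine / k-NN queries."""

    def __init__(self, vectors: Mapping[str, np.ndarray]) -> None:
        if not vectors:
            raise ParameterError("empty vector store")
        dims = {v.shape for v in vectors.values()}
        if len(dims) != 1:
            raise ParameterError(f"inconsistent vector shapes: {dims}")
        self._vectors = {cui: np.asarray(v, dtype=float) for cui, v in vectors.items()}
        self.dim = next(iter(self._vectors.values())).size
        self._cuis = sorted(self._vectors)
        matrix = np.vstack([self._vectors[c] for c in self._cuis])
        norms = np.linalg.norm(matrix, axis=1)
        nonzero = norms > 0
        matrix[nonzero] /= norms[nonzero, None]
        self._matrix = matrix  # rows unit (or zero): row @ unit query = cosine

    def vector(self, cui: str) -> np.ndarray:
        try:
            return self._vectors[cui]
        except KeyError:
            raise KeyError(f"unknown CUI {cui!r}") from None

    def cuis(self) -> List[str]:
        return list(self._cuis)

    def __contains__(self, cui: str) -> bool:
        return cui in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)


def build_concept_vectors(
    corpus: ConceptCorpus, docs: DocumentVectorStore
) -> SemanticVectorStore:
    """Reflective step: concept vector = normalized sum of the vectors of the
    documents containing the concept (document membership is binary; within-
    document mention multiplicity already acted through the local weight)."""
    containing: Dict[str, List[Tuple[str, str]]] = {}
    for doc in corpus:
        key = (doc.patient_id, doc.doc_id)
        for cui in set(doc.cuis):
            containing.setdefault(cui, []).append(key)
    vectors: Dict[str, np.ndarray] = {}
    for cui, keys in containing.items():
        raw = np.zeros(docs.dim)
        for key in keys:
            raw += docs.vector(*key)
        norm = float(np.linalg.norm(raw))
        if norm == 0.0:
            logger.warning("concept %s has zero semantic vector", cui)
            vectors[cui] = raw
        else:
            vectors[cui] = raw / norm
    return SemanticVectorStore(vectors)


def build_semantic_vectors(
    corpus: ConceptCorpus,
    dim: int = DEFAULT_DIM,
    nonzeros: int = DEFAULT_NONZEROS,
    master_seed: int = 0,
) -> SemanticVectorStore:
    """Convenience composition: elemental vectors -> log-entropy weights ->
    document vectors -> concept vectors."""
    elemental = ElementalVectorStore(dim=dim, nonzeros=nonzeros, master_seed=master_seed)
    weights = log_entropy_weights(corpus)
    docs = build_document_vectors(corpus, elemental, weights)
    return build_concept_vectors(corpus, docs)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors; 0 if either is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError(f"vector length mismatch: {a.shape} vs {b.shape}")
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def nearest_neighbors(
    store: SemanticVectorStore,
    cui: str,
    k: int,
    exclude: Iterable[str] = (),
) -> List[Tuple[str, float]]:
    """Top-k concepts by cosine to ``cui``, excluding the query itself and
    ``exclude``; descending cosine, ties broken by ascending CUI."""
    if k < 0:
        raise ParameterError(f"k must be >= 0, got {k}")
    query = store.vector(cui)  # KeyError if unknown
    if k == 0:
        return []
    excluded: Set[str] = set(exclude)
    excluded.add(cui)
    qnorm = float(np.linalg.norm(query))
    if qnorm == 0.0:
        sims = np.zeros(len(store))
    else:
        # stored non-zero vectors are unit norm; zero vectors yield cosine 0
        sims = store._matrix @ (query / qnorm)
    candidates = [
        (c, float(s)) for c, s in zip(store.cuis(), sims) if c not in excluded
    ]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates[:k]
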