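"""Core domain types shared across the pipeline.

The pipeline consumes the output shape of an automated clinical coder
(e.g. MetaMap): per-document lists of UMLS Concept Unique Identifiers
(CUIs) with extraction confidence scores in [0, 1000], grouped by
patient; plus a relation knowledge base of (subject, predicate, object,
source) triples emulating UMLS Metathesaurus relations and SemRep
literature predications.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

from .errors import ValidationError

_CUI_RE = re.compile(r"^C\d+$")

#: Gold phenotype labels: patient_id -> condition present.
GoldLabels = Dict[str, bool]


class Source(str, Enum):
    """Provenance of a relation triple: curated thesaurus or mined literature."""

    THESAURUS = "THESAURUS"
    LITERATURE = "LITERATURE"


@dataclass(frozen=True)
class ConceptMention:
    """One extracted concept instance: a CUI plus the coder's confidence (0-1000)."""

    cui: str
    confidence: int

    def __post_init__(self) -> None:
        if not self.cui or not _CUI_RE.match(self.cui):
            raise ValidationError(f"invalid CUI {self.cui!r} (expected C followed by digits)")
        if not 0 <= self.confidence <= 1000:
            raise ValidationError(
                f"confidence {self.confidence} for {self.cui} outside [0, 1000]"
            )


@dataclass(frozen=True)
class PatientDocument:
    """One clinical note for one patient, as a bag of concept mentions.

    Repeated mentions of the same CUI within a document are allowed and
    preserved; term-frequency weighting downstream depends on them.
    """

    patient_id: str
    doc_id: str
    mentions: Tuple[ConceptMention, ...]

    def __post_init__(self) -> None:
        if not self.patient_id or not self.doc_id:
            raise ValidationError("patient_id and doc_id must be non-empty")
        object.__setattr__(self, "mentions", tuple(self.mentions))

    @property
    def cuis(self) -> Tuple[str, ...]:
        return tuple(m.cui for m in self.mentions)


class ConceptCorpus:
    """A multi-patient collection of concept-coded documents.

    ``vocabulary`` is always the union of mention CUIs; ``(patient_id,
    doc_id)`` pairs are unique. Documents keep their insertion order.
    """

    def __init__(self, documents: Iterable[PatientDocument]) -> None:
        self.documents: List[PatientDocument] = list(documents)
        if not self.documents:
            raise ValidationError("empty corpus: at least one document required")
        seen = set()
        for doc in self.documents:
            key = (doc.patient_id, doc.doc_id)
            if key in seen:
                raise ValidationError(f"duplicate document {key}")
            seen.add(key)
        self.vocabulary: frozenset[str] = frozenset(
            m.cui for doc in self.documents for m in doc.mentions
        )

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[PatientDocument]:
        return iter(self.documents)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ConceptCorpus) and self.documents == other.documents

    def patient_ids(self) -> List[str]:
        """Distinct patient ids in first-appearance order."""
        out: List[str] = []
        seen = set()
        for doc in self.documents:
            if doc.patient_id not in seen:
                seen.add(doc.patient_id)
                out.append(doc.patient_id)
        return out

    def documents_of(self, patient_id: str) -> List[PatientDocument]:
        docs = [d for d in self.documents if d.patient_id == patient_id]
        if not docs:
            raise KeyError(f"unknown patient_id {patient_id!r}")
        return docs


@dataclass(frozen=True)
class RelationTriple:
    """A (subject, predicate, object) relation with its source database."""

    subject: str
    predicate: str
    object: str
    source: Source

    def __post_init__(self) -> None:
        if not self.predicate:
            raise ValidationError("predicate must be non-empty")
        if not isinstance(self.source, Source):
            object.__setattr__(self, "source", Source(self.source))


@dataclass(frozen=True)
class PredictionResult:
    """One patient's phenotype call with the raw seed-activation evidence."""

    patient_id: str
    seed_activation: float
    label: bool
    method: str = "GRAPH"  # GRAPH | BASELINE


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvaluationMetrics:
    precision: float
    recall: float
    f1: float
    accuracy: float
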