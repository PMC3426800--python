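"""Synthetic concept corpora with planted seed-associated structure.

No deposited clinical corpus exists for this method (clinical data
warehouses are private), so end-to-end behavior is exercised on fully
synthetic cohorts that emulate the statistical structure the method
assumes: a seed phenotype concept, a cluster of concepts genuinely
associated with it (mentioned far more often in case records than in
control records), and a large background vocabulary mentioned uniformly
by everyone. A consistent relation knowledge base supports a
configurable share of the (seed, associated) and (associated,
associated) pairs, split between thesaurus and literature sources, so
the knowledge filter's effect (noise-edge removal) is observable.

``occult_seed_mentions`` models the motivating real-world failure of
code- or mention-based phenotyping: for a share of case patients every
explicit seed mention is deleted while associated-concept mentions
remain — exactly the patients a mention-presence baseline must miss and
graph inference can recover.

Mentions are sampled per document (not per patient) so term-frequency
weighting sees real variance; generation is a pure function of the
configuration, including its RNG seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Set, Tuple

import numpy as np

from .errors import ValidationError
from .knowledge import KnowledgeBase
from .types import (
    ConceptCorpus,
    ConceptMention,
    GoldLabels,
    PatientDocument,
    RelationTriple,
    Source,
)

__all__ = ["SimulationConfig", "generate", "occult_seed_mentions"]

_THESAURUS_PREDICATES = ("ISA", "RB", "RN", "RO")
_LITERATURE_PREDICATES = ("TREATS", "DIAGNOSES", "PROCESS_OF", "ASSOCIATED_WITH", "AFFECTS")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the scale of the method's published evaluation (428
    patients, 19.2% prevalence) with per-document mention probabilities
    chosen to plant a strong but not degenerate association signal.
    """

    n_patients: int = 428
    docs_per_patient: Tuple[int, int] = (2, 6)  # inclusive range
    prevalence: float = 0.192
    seed_cui: str = "C0006142"
    n_associated: int = 12
    n_background: int = 200
    p_mention_seed_given_case: float = 0.6
    p_mention_assoc_given_case: float = 0.8
    p_mention_assoc_given_control: float = 0.05
    p_mention_background: float = 0.03
    confidence_range: Tuple[int, int] = (600, 1000)  # inclusive
    kb_support_fraction: float = 1.0
    kb_background_triples: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        lo, hi = self.docs_per_patient
        if not 1 <= lo <= hi:
            raise ValidationError(f"bad docs_per_patient range {self.docs_per_patient}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError("prevalence must be in (0, 1)")
        if self.n_associated < 1:
            raise ValidationError("n_associated must be >= 1")
        if self.n_background < 0:
            raise ValidationError("n_background must be >= 0")
        for name in (
            "p_mention_seed_given_case",
            "p_mention_assoc_given_case",
            "p_mention_assoc_given_control",
            "p_mention_background",
            "kb_support_fraction",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if self.p_mention_assoc_given_case < self.p_mention_assoc_given_control:
            raise ValidationError(
                "planted signal must be nonnegative: "
                "p_mention_assoc_given_case < p_mention_assoc_given_control"
            )
        clo, chi = self.confidence_range
        if not 0 <= clo <= chi <= 1000:
            raise ValidationError(f"bad confidence_range {self.confidence_range}")

    @property
    def associated_cuis(self) -> List[str]:
        return [f"C9{i:06d}" for i in range(1, self.n_associated + 1)]

    @property
    def background_cuis(self) -> List[str]:
        return [f"C8{i:06d}" for i in range(1, self.n_background + 1)]


def _confidence(rng: np.random.Generator, config: SimulationConfig) -> int:
    lo, hi = config.confidence_range
    return int(rng.integers(lo, hi + 1))


def generate(
    config: SimulationConfig,
) -> Tuple[ConceptCorpus, KnowledgeBase, GoldLabels]:
    """Sample a cohort: corpus, relation knowledge base, gold labels.

    Cases (probability ``prevalence``) mention the seed per document
    with ``p_mention_seed_given_case`` and each associated concept with
    ``p_mention_assoc_given_case``; controls never mention the seed and
    mention associated concepts at the control rate. Background
    concepts are mentioned uniformly by everyone. A document that
    samples no mention at all receives one forced background mention
    (the per-mention interchange format cannot represent an empty
    note). Deterministic given ``rng_seed``.
    """
    config.validate()
    if config.n_background == 0 and config.n_associated == 0:
        raise ValidationError("empty vocabulary")
    rng = np.random.default_rng(config.rng_seed)
    associated = config.associated_cuis
    background = config.background_cuis

    documents: List[PatientDocument] = []
    gold: GoldLabels = {}
    width = max(4, len(str(config.n_patients)))
    lo, hi = config.docs_per_patient
    for i in range(1, config.n_patients + 1):
        pid = f"P{i:0{width}d}"
        case = bool(rng.random() < config.prevalence)
        gold[pid] = case
        n_docs = int(rng.integers(lo, hi + 1))
        for j in range(1, n_docs + 1):
            mentions: List[ConceptMention] = []
            if case and rng.random() < config.p_mention_seed_given_case:
                mentions.append(
                    ConceptMention(config.seed_cui, _confidence(rng, config))
                )
            p_assoc = (
                config.p_mention_assoc_given_case
                if case
                else config.p_mention_assoc_given_control
            )
            for cui in associated:
                if rng.random() < p_assoc:
                    mentions.append(ConceptMention(cui, _confidence(rng, config)))
            for cui in background:
                if rng.random() < config.p_mention_background:
                    mentions.append(ConceptMention(cui, _confidence(rng, config)))
            if not mentions:
                forced = background[int(rng.integers(len(background)))] if background else associated[0]
                mentions.append(ConceptMention(forced, _confidence(rng, config)))
            documents.append(
                PatientDocument(patient_id=pid, doc_id=f"D{j:03d}", mentions=tuple(mentions))
            )

    corpus = ConceptCorpus(documents)
    kb = _generate_kb(rng, config, associated, background)
    return corpus, kb, gold


def _generate_kb(
    rng: np.random.Generator,
    config: SimulationConfig,
    associated: List[str],
    background: List[str],
) -> KnowledgeBase:
    pairs: List[Tuple[str, str]] = [(config.seed_cui, a) for a in associated]
    pairs += [
        (associated[i], associated[j])
        for i in range(len(associated))
        for j in range(i + 1, len(associated))
    ]
    if config.kb_background_triples and len(background) >= 2:
        # optional noise triples so the filter's selectivity can be probed
        n_noise = len(background) // 10
        idx = rng.choice(len(background), size=(n_noise, 2))
        pairs += [
            (background[a], background[b]) for a, b in idx if a != b
        ]
    triples: Set[RelationTriple] = set()
    for u, v in pairs:
        if rng.random() >= config.kb_support_fraction:
            continue
        if rng.random() < 0.5:
            source = Source.THESAURUS
            predicate = _THESAURUS_PREDICATES[int(rng.integers(len(_THESAURUS_PREDICATES)))]
        else:
            source = Source.LITERATURE
            predicate = _LITERATURE_PREDICATES[int(rng.integers(len(_LITERATURE_PREDICATES)))]
        triples.add(RelationTriple(subject=u, predicate=predicate, object=v, source=source))
    return KnowledgeBase(triples)


def occult_seed_mentions(
    corpus: ConceptCorpus, gold: GoldLabels, seed_cui: str, fraction: float
) -> ConceptCorpus:
    """Delete every seed-CUI mention for a ``fraction`` share of case patients.

    The occulted cases are the first ceil(fraction * n_cases) case ids
    in sorted order, so the operation is a pure function of its inputs.
    Documents left with no mentions are dropped; associated-concept
    mentions are untouched, so graph inference can still recover these
    patients while a mention-presence baseline cannot.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"fraction must be in [0, 1], got {fraction}")
    cases = sorted(pid for pid, positive in gold.items() if positive)
    n_occult = math.ceil(fraction * len(cases))
    occulted = set(cases[:n_occult])
    documents: List[PatientDocument] = []
    for doc in corpus:
        if doc.patient_id in occulted:
            kept = tuple(m for m in doc.mentions if m.cui != seed_cui)
            if not kept:
                continue
            documents.append(
                PatientDocument(doc.patient_id, doc.doc_id, kept)
            )
        else:
            documents.append(doc)
    return ConceptCorpus(documents)
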