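"""Spreading-activation inference on the curated concept graph.

Each patient's record seeds the graph: every node's starting activation
is the sum of the linearly normalized (score/1000) extraction
confidences of that concept over all of the patient's notes; concepts
absent from the record start at 0. Activation then spreads
synchronously for a fixed number of steps (default 3): at each step a
connected node redistributes its entire activation to its neighbors in
proportion to incident-edge weight ("sum of incoming minus spread out"
reduces to full proportional redistribution), while isolated nodes keep
theirs. Total activation is conserved exactly, and the dynamics are
linear and monotone in the evidence because all weights are
nonnegative. The final activation of the seed node is the phenotype
signal; a patient is called positive when it exceeds the decision
threshold.

The threshold is the method's one free parameter. The default 0 labels
any patient with nonzero seed-component evidence positive; for cohorts
where related concepts also occur at a background rate among controls,
:func:`select_activation_threshold` offers an unsupervised data-driven
choice (two-means split of the log-transformed activation scores).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .errors import ParameterError, ValidationError
from .graph import ConceptGraph
from .knowledge import active_subgraph
from .types import PatientDocument, PredictionResult

logger = logging.getLogger(__name__)

#: Per-node nonnegative activation values for one patient.
ActivationState = Dict[str, float]

__all__ = [
    "ActivationState",
    "normalize_confidence",
    "initial_activation",
    "spread_step",
    "spread",
    "classify_patient",
    "baseline_classify",
    "select_activation_threshold",
]


def normalize_confidence(score: int) -> float:
    """Map a coder confidence score in [0, 1000] linearly to [0, 1]."""
    if not 0 <= score <= 1000:
        raise ValidationError(f"confidence {score} outside [0, 1000]")
    return score / 1000.0


def _check_single_patient(documents: Sequence[PatientDocument]) -> None:
    ids = {d.patient_id for d in documents}
    if len(ids) > 1:
        raise ParameterError(f"documents span multiple patients: {sorted(ids)}")


def initial_activation(
    graph: ConceptGraph, documents: Sequence[PatientDocument]
) -> ActivationState:
    """Starting activation: per graph node, the sum of normalized confidences
    of that CUI over every mention instance in the patient's documents.

    Mentions of CUIs outside the graph are ignored; graph nodes never
    mentioned start at 0.
    """
    _check_single_patient(documents)
    state: ActivationState = {node: 0.0 for node in graph.g.nodes}
    for doc in documents:
        for m in doc.mentions:
            if m.cui in state:
                state[m.cui] += normalize_confidence(m.confidence)
    return state


def _check_state(graph: ConceptGraph, state: Mapping[str, float]) -> None:
    missing = set(graph.g.nodes) - set(state)
    if missing:
        raise ParameterError(f"state missing nodes: {sorted(missing)[:5]}")


def spread_step(
    graph: ConceptGraph, state: ActivationState, retain: float = 0.0
) -> ActivationState:
    """One synchronous spreading step.

    A node u with positive total incident weight S sends
    ``(1 - retain) * a(u) * w(u, v) / S`` to each neighbor v and keeps
    ``retain * a(u)``; isolated nodes (no incident edges, or all-zero
    incident weight) keep their activation unchanged. Total activation
    is conserved exactly. Negative edge weights are rejected.
    """
    if not 0.0 <= retain <= 1.0:
        raise ParameterError(f"retain must be in [0, 1], got {retain}")
    _check_state(graph, state)
    g = graph.g
    strength: Dict[str, float] = {}
    for u in g.nodes:
        s = 0.0
        for _, v, w in g.edges(u, data="weight"):
            if w < 0:
                raise ValidationError(f"negative edge weight on ({u}, {v}): {w}")
            s += w
        strength[u] = s
    new: ActivationState = {}
    for u in g.nodes:
        new[u] = state[u] if strength[u] == 0.0 else retain * state[u]
    for u in g.nodes:
        if strength[u] == 0.0:
            continue
        share = (1.0 - retain) * state[u] / strength[u]
        for _, v, w in g.edges(u, data="weight"):
            new[v] += share * w
    return new


def spread(
    graph: ConceptGraph, state: ActivationState, steps: int = 3, retain: float = 0.0
) -> ActivationState:
    """``steps``-fold composition of :func:`spread_step`; steps=0 is identity."""
    if steps < 0:
        raise ParameterError(f"steps must be >= 0, got {steps}")
    current = dict(state)
    for _ in range(steps):
        current = spread_step(graph, current, retain=retain)
    return current


def classify_patient(
    graph: ConceptGraph,
    documents: Sequence[PatientDocument],
    steps: int = 3,
    threshold: float = 0.0,
    retain: float = 0.0,
) -> PredictionResult:
    """Seed the graph with the patient's mentions, spread, read the seed.

    Inference runs on the seed's connected component: nodes outside it
    cannot exchange activation with the seed, so their mentions never
    affect the readout. The label is positive iff the final seed
    activation strictly exceeds ``threshold``.
    """
    _check_single_patient(documents)
    active = active_subgraph(graph)
    state = initial_activation(active, documents)
    final = spread(active, state, steps=steps, retain=retain)
    seed_activation = final[graph.seed]
    patient_id = documents[0].patient_id if documents else ""
    return PredictionResult(
        patient_id=patient_id,
        seed_activation=seed_activation,
        label=seed_activation > threshold,
        method="GRAPH",
    )


def baseline_classify(
    documents: Sequence[PatientDocument], seed: str
) -> PredictionResult:
    """Coder-as-classifier baseline: positive iff the seed CUI is mentioned
    anywhere in the patient's record (presence, not score, decides).

    ``seed_activation`` reports the summed normalized seed confidence
    for inspection; it plays no part in the decision.
    """
    _check_single_patient(documents)
    total = 0.0
    present = False
    for doc in documents:
        for m in doc.mentions:
            if m.cui == seed:
                present = True
                total += normalize_confidence(m.confidence)
    patient_id = documents[0].patient_id if documents else ""
    return PredictionResult(
        patient_id=patient_id, seed_activation=total, label=present, method="BASELINE"
    )


def select_activation_threshold(scores: Sequence[float], random_state: int = 0) -> float:
    """Unsupervised decision threshold from the cohort's activation scores.

    Fits two-cluster k-means to log1p-transformed scores and returns the
    midpoint between the cluster centers, mapped back to the activation
    scale. With fewer than two distinct scores, returns the maximum
    score (so nothing is labeled positive by a strict comparison).
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ParameterError("cannot select a threshold from no scores")
    if np.unique(arr).size < 2:
        return float(arr.max())
    from sklearn.cluster import KMeans

    x = np.log1p(arr).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(x)
    midpoint = float(np.mean(km.cluster_centers_))
    return float(np.expm1(midpoint))
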