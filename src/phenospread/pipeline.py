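"""End-to-end pipeline: vectors -> graph -> filter -> phenotype -> evaluate.

Library-level composition of the stages, used both programmatically and
by the command-line wrapper. Every stage writes its artifact with a
temp-then-rename, and each run drops a JSON manifest (tool version,
resolved parameters, input checksums, timestamp) next to its outputs so
a run can be audited and reproduced.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from . import __version__
from .activation import (
    baseline_classify,
    classify_patient,
    select_activation_threshold,
)
from .errors import ParameterError
from .evaluation import confusion, format_percent, metrics
from .graph import ConceptGraph, build_bfs_graph
from .io_formats import (
    atomic_write,
    read_concept_corpus,
    read_gold_labels,
    read_graph,
    read_knowledge_base,
    read_vector_store,
    sha256_of,
    write_graph,
    write_predictions,
    write_vector_store,
)
from .knowledge import KnowledgeBase, filter_graph
from .rri import build_semantic_vectors
from .types import ConceptCorpus, GoldLabels, PredictionResult

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "phenotype_corpus", "baseline_corpus", "write_manifest", "write_report"]

Threshold = Union[float, str]  # a number, or "auto"


def write_manifest(
    path: Path | str,
    stage: str,
    parameters: Dict[str, object],
    inputs: Sequence[Path | str] = (),
) -> None:
    """Audit sidecar: version, resolved parameters, input checksums, timestamp."""
    manifest = {
        "tool": "phenospread",
        "version": __version__,
        "stage": stage,
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in parameters.items()},
        "inputs": {str(p): sha256_of(p) for p in inputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    with atomic_write(path) as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _resolve_threshold(threshold: Threshold, activations: Sequence[float]) -> float:
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ParameterError(f"threshold must be a number or 'auto', got {threshold!r}")
        value = select_activation_threshold(activations)
        logger.info("auto-selected activation threshold: %g", value)
        return value
    return float(threshold)


def phenotype_corpus(
    graph: ConceptGraph,
    corpus: ConceptCorpus,
    steps: int = 3,
    threshold: Threshold = 0.0,
    retain: float = 0.0,
) -> List[PredictionResult]:
    """Graph-method predictions for every patient in the corpus.

    ``threshold="auto"`` selects the unsupervised two-means threshold
    from the cohort's seed-activation distribution before labeling.
    """
    raw = [
        classify_patient(graph, corpus.documents_of(pid), steps=steps, retain=retain)
        for pid in corpus.patient_ids()
    ]
    t = _resolve_threshold(threshold, [r.seed_activation for r in raw])
    return [
        PredictionResult(r.patient_id, r.seed_activation, r.seed_activation > t, "GRAPH")
        for r in raw
    ]


def baseline_corpus(corpus: ConceptCorpus, seed_cui: str) -> List[PredictionResult]:
    """Mention-presence baseline predictions for every patient."""
    return [
        baseline_classify(corpus.documents_of(pid), seed_cui)
        for pid in corpus.patient_ids()
    ]


def write_report(
    path: Path | str,
    rows: Dict[str, tuple],
) -> None:
    """TSV report: per method, confusion counts and one-decimal percent metrics."""
    header = [
        "method", "tp", "fp", "tn", "fn",
        "precision_pct", "recall_pct", "f1_pct", "accuracy_pct",
    ]
    with atomic_write(path) as fh:
        fh.write("\t".join(header) + "\n")
        for method in sorted(rows):
            cm, m = rows[method]
            fh.write(
                f"{method}\t{cm.tp}\t{cm.fp}\t{cm.tn}\t{cm.fn}\t"
                f"{format_percent(m.precision)}\t{format_percent(m.recall)}\t"
                f"{format_percent(m.f1)}\t{format_percent(m.accuracy)}\n"
            )


@dataclass
class PipelineConfig:
    """Resolved parameters for one end-to-end run.

    Defaults are the published operating point where one exists: 1000
    dimensions, branching 6, depth 3, 3 spreading steps, seed C0006142.
    """

    corpus: Path
    kb: Path
    out_dir: Path
    gold: Optional[Path] = None
    seed_cui: str = "C0006142"
    dim: int = 1000
    nonzeros: int = 10
    master_seed: int = 0
    branching: int = 6
    depth: int = 3
    min_cosine: float = 0.0
    cross_edges: bool = False
    steps: int = 3
    threshold: Threshold = 0.0
    retain: float = 0.0


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the full pipeline, persisting every stage artifact.

    Returns a summary dict with artifact paths and, when gold labels
    were supplied, the evaluation metrics for both methods. Raises on
    the first failing stage; no partially written final artifact is
    left behind.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/5: building semantic vectors")
    corpus = read_concept_corpus(config.corpus)
    store = build_semantic_vectors(
        corpus, dim=config.dim, nonzeros=config.nonzeros, master_seed=config.master_seed
    )
    vectors_path = out / "vectors.tsv"
    write_vector_store(
        store,
        vectors_path,
        metadata={
            "nonzeros": config.nonzeros,
            "master_seed": config.master_seed,
            "corpus_checksum": sha256_of(config.corpus),
        },
    )

    logger.info("stage 2/5: building BFS nearest-neighbor graph")
    graph = build_bfs_graph(
        store,
        config.seed_cui,
        branching=config.branching,
        max_depth=config.depth,
        min_cosine=config.min_cosine,
        cross_edges=config.cross_edges,
    )
    graph_path = out / "graph.tsv"
    write_graph(graph, graph_path)

    logger.info("stage 3/5: knowledge-filtering the graph")
    kb = KnowledgeBase(read_knowledge_base(config.kb))
    filtered = filter_graph(graph, kb)
    filtered_path = out / "graph.filtered.tsv"
    write_graph(filtered, filtered_path)

    logger.info("stage 4/5: phenotyping %d patients", len(corpus.patient_ids()))
    graph_preds = phenotype_corpus(
        filtered, corpus, steps=config.steps, threshold=config.threshold, retain=config.retain
    )
    predictions_path = out / "predictions.tsv"
    write_predictions(graph_preds, predictions_path)
    base_preds = baseline_corpus(corpus, config.seed_cui)
    baseline_path = out / "baseline_predictions.tsv"
    write_predictions(base_preds, baseline_path)

    summary: Dict[str, object] = {
        "vectors": str(vectors_path),
        "graph": str(graph_path),
        "filtered_graph": str(filtered_path),
        "predictions": str(predictions_path),
        "baseline_predictions": str(baseline_path),
        "n_patients": len(corpus.patient_ids()),
    }

    if config.gold is not None:
        logger.info("stage 5/5: evaluating against gold labels")
        gold = read_gold_labels(config.gold)
        rows = {}
        for method, preds in (("GRAPH", graph_preds), ("BASELINE", base_preds)):
            cm = confusion(preds, gold)
            rows[method] = (cm, metrics(cm))
        report_path = out / "report.tsv"
        write_report(report_path, rows)
        summary["report"] = str(report_path)
        summary["metrics"] = {
            method: {"confusion": asdict(cm), "metrics": asdict(m)}
            for method, (cm, m) in rows.items()
        }

    params = {k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(config).items()}
    inputs = [config.corpus, config.kb] + ([config.gold] if config.gold else [])
    write_manifest(out / "run.manifest.json", "run", params, inputs)
    return summary
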