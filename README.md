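# phenospread

Unsupervised graph-based **high-throughput phenotyping** from the output of an
automated clinical concept coder.

Clinical data warehouses hold millions of free-text notes, but the question
research actually needs answered is about the *patient*, not the document:
"did this patient ever have breast cancer?" — not "does this note mention
breast cancer?". Billing codes notoriously under-report (at some institutions
only about half of true cases ever receive the corresponding code), and
mention-presence coding both misses patients whose charts carry only indirect
evidence and over-calls patients whose notes mention a condition in a family
history. `phenospread` implements a fully unsupervised alternative that needs
no training labels and no disease-specific rules: it reads the same coder
output (UMLS CUI mentions with confidence scores 0–1000 per document, grouped
by patient) and combines three knowledge sources — the corpus itself, a
relation thesaurus, and literature predications — into a per-patient call.

## Method

1. **Reflective random indexing (RRI).** Every CUI gets a deterministic
   sparse ternary *elemental* vector e(i) ∈ {−1,0,+1}^d (d = 1000, 10
   nonzeros). A document vector is the normalized log-entropy-weighted
   superposition

   d(j) = normalize( Σᵢ log(1 + tfᵢⱼ) · gᵢ · e(i) ),
   gᵢ = 1 + Σⱼ pᵢⱼ log pᵢⱼ / log n,  pᵢⱼ = tfᵢⱼ / gfᵢ,

   and the *semantic* vector of a concept is the normalized sum of the
   vectors of the documents containing it. Cosine similarity between
   semantic vectors captures second-order association: two concepts that
   never co-occur can still be close.
2. **Nearest-neighbor graph.** From a seed phenotype CUI (default
   C0006142, malignant neoplasm of breast), a breadth-first expansion adds
   up to 6 nearest neighbors per node for at most 3 levels (≤ 1+6+36+216 =
   259 nodes), edge weight = cosine.
3. **Knowledge filtering.** An edge survives only if *any* relation between
   its endpoints exists in the thesaurus (labels shown as `UMLS:...`) or in
   the literature triple set (bare labels). Orphaned nodes are kept but can
   no longer influence the seed.
4. **Spreading activation.** For each patient, every graph node starts at
   the sum of the patient's normalized confidences (score/1000) for that
   CUI; activation then spreads synchronously for 3 steps, each connected
   node redistributing its activation to neighbors proportionally to edge
   weight (total activation is conserved; the dynamics are linear). The
   final seed-node activation is the phenotype signal; the patient is
   positive when it exceeds the decision threshold.

The threshold is the method's one free parameter (default 0;
`select_activation_threshold` provides an unsupervised two-means choice —
see `docs/methods.md`). The baseline for comparison is the coder itself:
positive iff the seed CUI is mentioned anywhere in the record.

## Worked example

No public clinical corpus exists for this task, so the package ships a
synthetic-cohort generator with planted structure. `examples/` contains one
narrative script per capability; for instance:

```bash
$ python examples/02_build_and_filter_graph.py
BFS graph: GraphStats(node_count=11, edge_count=10, seed_component_node_count=11, seed_component_edge_count=10)
after knowledge filtering: GraphStats(node_count=11, edge_count=10, seed_component_node_count=11, seed_component_edge_count=10)
planted cluster recovered: 10/12
sample labeled edges:
  C0006142 -- C9000012  weight 0.968  label ASSOCIATED_WITH
  C0006142 -- C9000011  weight 0.964  label UMLS:RB
```

The graph grown from the seed found 10 of the 12 planted associated
concepts; every kept edge carries its cosine weight and a relation label
traceable to the knowledge base. And the capability the method exists for —
calling a true case whose record never mentions the phenotype explicitly:

```bash
$ python examples/03_phenotype_patients.py
patient P0001 (true case, seed mentions occulted):
  baseline: label=False  (seed mentioned? no)
  graph:    label=True  seed activation 5.14
```

The same pipeline is scriptable from the shell:

```bash
phenospread simulate --out-dir cohort --n-patients 428 --rng-seed 1
phenospread run --corpus cohort/corpus.tsv --kb cohort/kb.tsv \
    --gold cohort/labels.tsv --threshold auto --out-dir results
```

## Layout

- `src/phenospread/` — library: `io_formats` (TSV/GraphML interchange),
  `rri` (embeddings), `graph` (BFS construction), `knowledge` (edge
  filtering), `activation` (spreading + classification), `evaluation`,
  `simulate` (synthetic cohorts), `experiments`, `pipeline`, `cli`.
- `examples/` — one short narrative script per capability.
- `tests/` — pytest suite with independent brute-force oracles.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
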