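# Methods

## Problem and model

Given per-patient collections of coder output — (CUI, confidence) mention
instances per clinical note — decide for every patient whether a target
phenotype (the *seed* concept) is part of their history. The method is
unsupervised: it uses the corpus's own co-occurrence statistics, a relation
thesaurus, and literature predications, but no labeled patients.

The pipeline has four stages, each a pure function of its inputs and the
stated parameters.

### 1. Reflective random indexing

Concept vocabulary size is unbounded (the UMLS has millions of CUIs), so
concepts are embedded by random projection rather than by explicit
dimensions. Each CUI receives an *elemental* vector: dimension `dim`
(default 1000) with `nonzeros` (default 10, even) nonzero entries, half +1
and half −1, positions drawn without replacement by a generator keyed on a
SHA-256 hash of `(master_seed, cui)`. Keying on the pair makes the mapping
counter-based: the vector of a CUI is independent of the order in which
vectors are requested, and no elemental store ever needs to be persisted.
Random ternary vectors of this sparsity are near-orthogonal in expectation
(mean |cosine| ≈ 0.01 at the defaults; the suite verifies < 0.05 over all
4950 pairs of 100 vectors).

Document vectors are log-entropy-weighted superpositions: with tf_ij the
count of CUI i in document j, gf_i = Σ_j tf_ij and n documents,

    local(i, j) = log(1 + tf_ij)          (natural log)
    g_i         = 1 + Σ_j p_ij log(p_ij) / log(n),   p_ij = tf_ij / gf_i
    d(j)        = normalize( Σ_i local(i, j) · g_i · e(i) )

g_i = 1 for a concept confined to one document, and 0 for one spread
uniformly over all documents (computed g is clamped into [0, 1]; values
below 1e-12 snap to exactly 0 so uniform concepts drop out rather than
surviving as rounding noise that normalization would re-amplify). For a
single-document corpus g ≡ 1 by convention. A document whose every concept
has g = 0 yields the zero vector, kept with a logged warning so degenerate
notes do not abort a corpus-scale run.

The *reflective* step builds one semantic vector per CUI as the normalized
unweighted sum of the vectors of the documents containing it; membership is
binary (within-document multiplicity already acted through the local
weight). One reflective iteration is performed — elemental → document →
concept — which suffices to capture second-order association: concepts that
never co-occur but share containing-document neighborhoods get similar
vectors (property-tested).

Relatedness is the cosine between semantic vectors; cosine with a zero
vector is defined as 0. Nearest-neighbor queries are exact full scans
(cohorts at this scale need no approximate index), ordered by descending
cosine with ties broken by ascending CUI for determinism.

### 2. Breadth-first nearest-neighbor graph

From the seed CUI, frontier nodes are processed in insertion order; each
queries its top-`branching` (default 6) neighbors and keeps those with
cosine ≥ `min_cosine` (default 0, which also guarantees nonnegative edge
weights for the spreading dynamics). A previously unseen neighbor joins one
BFS level deeper with an edge weighted by the cosine; an already-present
neighbor is skipped and, by default, contributes no new edge, keeping the
construction near-tree. The optional `cross_edges` flag instead links
already-present pairs. Expansion stops after `max_depth` (default 3)
levels, so the graph holds at most 1 + b + b² + ... + b^d nodes (259 at the
defaults). The defaults mirror working-memory-sized expansion (6 items per
level, 3 levels); both are exposed.

### 3. Knowledge filtering

Cosine neighbors are related but not necessarily *meaningfully* related.
Each edge is checked against the relation knowledge base: any triple
connecting the two endpoints, in either direction, with any predicate, from
either source validates the edge. Unsupported edges are removed; nodes are
never removed (orphans simply cannot influence the seed). Surviving edges
are labeled: thesaurus predicates win over literature predicates when both
exist, and within a source the lexicographically smallest predicate is
chosen — a deterministic convention, since the databases impose no tie
rule. Thesaurus labels are rendered `UMLS:<predicate>`, literature labels
bare. Filtering is idempotent and only ever shrinks the edge set.
`active_subgraph` restricts to the seed's connected component, the only
part of the graph that can affect the readout.

### 4. Spreading activation and classification

Per patient, each graph node starts at the sum over all mention instances
of that CUI of confidence/1000. One synchronous step sends, from every node
u with positive total incident weight S_u, the share a(u)·w(u,v)/S_u to
each neighbor v ("incoming minus outgoing" reduces to exactly this full
proportional redistribution); isolated nodes — including the pathological
case of a node whose incident weights are all zero — keep their activation.
Total activation is conserved to 1e-9 (tested), and the dynamics are linear
and monotone in the evidence because weights are nonnegative. A
`retain` ∈ [0, 1] parameter generalizes to partial redistribution
(default 0, i.e. full). After `steps` (default 3) steps the seed node's
activation is the signal; the label is `activation > threshold`. Inference
runs on the seed component; mentions of nodes outside it provably cannot
change the readout.

**The decision threshold** is the method's genuinely free parameter: the
published account reads out the seed value but never states the cutoff that
produced its positive calls, so no value can be recovered. The default is
0 — any nonzero seed-component evidence counts — which is the natural
choice when related concepts are rare among controls. In cohorts where
associated concepts also occur at a background rate among unaffected
patients, threshold 0 over-calls; `select_activation_threshold` therefore
offers an unsupervised alternative chosen a priori: two-cluster k-means on
log1p-transformed cohort activations, returning the midpoint of the cluster
centers mapped back to the activation scale. It uses no gold labels. With
fewer than two distinct scores it returns the maximum (so a strict
comparison labels nothing positive). The replicated experiments and the
`--threshold auto` pipeline option use this rule.

The comparison baseline is the coder itself as a classifier: positive iff
the seed CUI is mentioned anywhere in the record (presence, not score).

## Synthetic cohorts

No public corpus exists for this task (clinical warehouses are private), so
the generator plants the statistical structure the method assumes:

| parameter | default | meaning |
|---|---|---|
| n_patients | 428 | cohort size (published evaluation scale) |
| prevalence | 0.192 | P(case) (published cohort fraction) |
| docs_per_patient | 2–6 | notes per patient, uniform |
| n_associated | 12 | planted seed-associated concepts |
| n_background | 200 | unrelated vocabulary |
| p_mention_seed_given_case | 0.6 / doc | explicit seed mention rate in case notes |
| p_mention_assoc_given_case | 0.8 / doc / concept | association signal, cases |
| p_mention_assoc_given_control | 0.05 / doc / concept | association noise, controls |
| p_mention_background | 0.03 / doc / concept | uniform background rate |
| confidence_range | 600–1000 | coder confidence, uniform integer |
| kb_support_fraction | 1.0 | share of planted pairs with a KB triple |

Cohort size and prevalence mirror the published evaluation; the association
probabilities are the strong-signal operating point (cases mention most of
the cluster in every note, controls rarely), chosen so the planted cluster
is recoverable yet controls still generate nonzero graph activation — the
regime where thresholding actually matters. Mentions are sampled per
document so tf-based weighting sees real variance; controls never mention
the seed; the KB never relates background concepts unless the
`kb_background_triples` flag is set, so the filter's effect is observable
as noise-edge removal. A document that samples no mention receives one
forced background mention, because the per-mention interchange format
cannot represent an empty note. Generation is a pure function of the
config, including `rng_seed`.

`occult_seed_mentions` deletes every seed mention for the first
⌈fraction·n⌉ case ids in sorted order (deterministic), modeling patients
whose histories are real but never explicitly restated — the population a
mention-presence baseline must miss.

What the generator does **not** emulate: clinical language and coder error
(beyond the confidence score), negation and family-history mentions (the
major source of baseline false positives on real data — absent here,
controls never mention the seed, so the synthetic baseline's precision is
unrealistically perfect and the published baseline's precision collapse is
not reproduced), correlated comorbidity structure, and vocabulary at UMLS
scale. Passing tests therefore demonstrate correctness of the machinery and
the qualitative superiority of graph inference under occulted explicit
mentions; they do not certify real-EHR operating characteristics.

## Numerical and design choices

- Elemental generation is deterministic per (master_seed, cui); identical
  inputs give bit-identical vector stores.
- Weight floats persist via `repr` in graph TSVs (bit-exact round trips)
  and 9 significant digits in vector stores.
- All tabular artifacts are UTF-8, LF, tab-separated with mandatory
  headers; readers fail loudly with line numbers rather than dropping rows.
- Graph TSV carries the seed and per-node depths as `#` comment lines so
  isolated nodes and BFS levels survive round trips; GraphML carries the
  same attributes.
- Stage outputs are written temp-then-rename; a failed stage leaves no
  partial artifact. Each run writes a JSON manifest (version, resolved
  parameters, input SHA-256 checksums, timestamp).
- Undefined evaluation metrics (zero denominators) are 0 with a warning,
  so threshold sweeps never crash; an all-zero confusion matrix is an
  error. Report percentages round half-away-from-zero to one decimal.
- Experiment replicate i derives its RNG seed as base_seed·1000 + i
  (mod 2³¹) for both the cohort and the elemental vectors.
- Problem sizes in the replicated experiments: 10 replicates of 428
  patients at dim 1000 — small enough to re-run interactively, large
  enough that binomial noise in prevalence and recovery stays a few
  percent.

## Known limitations

- Single seed concept per graph; no multi-phenotype inference.
- One reflective iteration; no permutation/order encoding; exact k-NN only.
- Predicate semantics are ignored by the filter (any relation validates an
  edge); predicate-aware weighting is deliberately out of scope.
- No negation or family-history handling: on real notes the baseline and
  the graph method both inherit the coder's false-positive mentions.
- The decision threshold remains cohort-dependent; the auto rule assumes a
  roughly bimodal activation distribution and will split noise when no
  signal exists.
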