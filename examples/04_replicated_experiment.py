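"""Replicated comparison of the graph method against mention-presence coding.

Runs three seeded end-to-end replicates at a reduced scale: generate a
cohort, embed, build and filter the graph, occult half the case patients'
seed mentions, phenotype everyone (unsupervised auto-threshold), and score
both methods against the gold labels.
"""

from phenospread import SimulationConfig
from phenospread.experiments import run_replicates

results = run_replicates(
    n_replicates=3,
    base_seed=5,
    occult_fraction=0.5,
    dim=500,
    config=SimulationConfig(n_patients=200),
)

print("seed   recovery   graph acc / F1      baseline acc / F1")
for r in results:
    print(
        f"{r.rng_seed}   {r.cluster_recovery:7.0%}   "
        f"{r.graph.accuracy:8.1%} / {r.graph.f1:5.1%}   "
        f"{r.baseline.accuracy:8.1%} / {r.baseline.f1:5.1%}"
    )
print(
    "\n'recovery' is the share of planted associated concepts the BFS graph"
    "\nfound. The graph method keeps high accuracy although half the case"
    "\nrecords never mention the phenotype concept; the baseline's recall"
    "\n(and hence F1) collapses on exactly those patients."
)
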