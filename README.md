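# mirflow

Prediction of microRNA–disease associations by maximum network information
flow.

Dysregulated microRNAs are involved in the onset and progression of many
complex diseases, but experimentally confirming which miRNA is tied to which
disease is slow and expensive. `mirflow` is for computational biologists who
want to rank candidate miRNAs for a disease of interest (or candidate
diseases for a miRNA) from heterogeneous data that already exists: known
miRNA–disease associations, miRNA functional similarity, disease
semantic/phenotypic similarity, and miRNA family/cluster membership.

## The model

The method builds an undirected, weighted **microRNAome–phenome network**
`UG = (V, E)` with three edge layers:

- **miRNA–miRNA** functional similarity edges, kept when the similarity is
  at least a threshold `α`. Similarity can be loaded precomputed or derived
  from target-gene sets as a Jaccard overlap
  `N_com / (N_i + N_j − N_com)` (Dice optional).
- **disease–disease** semantic/phenotypic similarity edges, kept at
  threshold `β`. Semantic similarity scores a disease pair by the
  information content of the MeSH ancestors they share:
  `IC(t) = −ln p(t)` with `p(t)` the fraction of disease DAGs containing
  term `t`, and
  `SS(A,B) = Σ_{t∈T_A∩T_B} (DV_A(t)+DV_B(t)) / (DV(A)+DV(B))`.
  Where a text-mined phenotypic similarity exists for an OMIM-mapped pair it
  is averaged with `SS`.
- **miRNA–disease** association edges with capacity
  `γ·(1 + η·R_p + σ·R_q)`, where `R_p` (`R_q`) is the fraction of the
  miRNA's family (genomic cluster) already associated with the disease —
  members of co-associated families and clusters carry more capacity.

To score candidates for a query, every undirected edge is split into two
opposite arcs with integer capacity `round(1000·w)`, an artificial source
feeds the query and every candidate drains into an artificial sink through
effectively infinite arcs. The exact maximum flow `f*` is computed with a
deterministic push-relabel algorithm, and the flow leaving each candidate
into the sink is its association score; candidates are returned as a ranked
list with rank ratios (rank / number of candidates, smaller = better).

Validation utilities reproduce the full protocol around the model:
leave-one-out and ab initio cross-validation with pooled rank-ratio ROC/PR
curves, F1-optimal thresholds, permutation null models, single-layer
ablations, exhaustive parameter grid search, hypergeometric enrichment of
prediction/database overlap, and (weighted) rank-average ensembling of
multiple predictors. A planted-module synthetic benchmark generator makes
everything testable without external downloads.

## Worked example

```python
from mirflow import ModelParams, assemble_network, generate_benchmark, prioritize

bench = generate_benchmark()            # planted synthetic inputs, seed 1
params = ModelParams()                  # alpha=0.1, beta=0.6, gamma=100, eta=6, sigma=10
network = assemble_network(bench.mirna_sim, bench.disease_sim, bench.assoc,
                           bench.families, bench.clusters, params)
known = bench.assoc.associated_mirnas("disease-001")
candidates = [m for m in bench.mirna_sim.labels if m not in known]
ranked = prioritize(network, "disease-001", candidates, params)
for e in ranked.entries[:3]:
    print(e.rank, e.candidate_id, e.score, round(e.rank_ratio, 3))
```

prints

```
1 mir-001 98667.0 0.017
2 mir-027 2056.0 0.034
3 mir-035 1966.0 0.051
```

`mir-001` receives ~98.7k flow units (capacities are weights × 1000): it is
linked to other diseases highly similar to the query, so nearly a full
association capacity reaches it; the next candidates receive flow only
through similarity edges and score an order of magnitude lower. Running
`examples/02_cross_validation.py` on the same benchmark reports a LOOCV
ROC AUC of 0.711 versus 0.571 for the harder ab initio setting, and
`examples/03_permutation_and_ablation.py` shows the AUC collapsing to
≈0.51 when the association layer is permuted. The remaining scripts in
`examples/` cover disease semantic similarity and rank-average ensembling.

A thin command line mirrors the library (`mirflow synth`, `sim-mirna`,
`sim-disease`, `prioritize`, `loocv`, `permute`, `ensemble`); see
`mirflow --help`.

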