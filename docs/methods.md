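# Methods

## Problem and model

Given known miRNA–disease associations and similarity structure on both
sides, the task is to rank candidate miRNAs for a query disease (or
candidate diseases for a query miRNA). The model is a capacitated network:
similarity and association edges carry capacity proportional to the strength
of the relation, and the association score of a candidate is the amount of
maximum source→sink flow it carries when the source is attached to the query
and every candidate drains into the sink through an effectively infinite
arc. Intuitively, a candidate scores highly when many high-capacity paths —
direct associations of similar diseases, similarity edges to associated
miRNAs, and longer mixed paths — connect it to the query. The key modelling
assumption is that functionally similar miRNAs tend to associate with
phenotypically similar diseases; the method can only work on data where
that holds.

## Network construction

Three layers form the undirected graph `UG`:

- miRNA similarity edges with weight `s ∈ [0,1]`, kept iff `s ≥ α`
  (default α = 0.1);
- disease similarity edges kept iff `s ≥ β` (default β = 0.6);
- association edges with weight `γ·(1 + η·R_p + σ·R_q)` (defaults γ = 100,
  η = 6, σ = 10), where `R_p`/`R_q` are the fractions of the miRNA's
  family/cluster members already associated with the disease.

The defaults are the grid-search optima for miRNA prioritization under
leave-one-out cross-validation; alternative optima for the other three
validation settings can be set explicitly. The thresholds exist because
low similarity values are dominated by noise; γ balances how much capacity
crosses between the two sides relative to flow within a side; η and σ have
little effect across their 1–10 range and mainly distinguish members of
co-associated families/clusters.

Design choices that were genuinely open:

- **Corrected association weight.** The functional forms adopted are
  `γ·(1+η·R_p)`, `γ·(1+σ·R_q)`, and `γ·(1+η·R_p+σ·R_q)` for dual
  membership. They satisfy the stated constraints (strictly above γ
  whenever a co-association ratio is positive, equal to γ at zero) and
  reduce smoothly to the base case. A miRNA in several families uses the
  family with the highest ratio (and likewise for clusters) — a
  deterministic, order-independent rule.
- **Family/cluster data never adds edges**; it only reweights existing
  association edges. Adding edges would alter the bipartite topology, which
  nothing in the model description requires.
- **Entities missing from a similarity matrix** are kept as
  association-only nodes (with a warning): dropping them would silently
  shrink the gold standard.

## Similarity measures

**miRNA target-overlap similarity.** Jaccard
`N_com/(N_i+N_j−N_com)` by default; Dice `2·N_com/(N_i+N_j)` is available
via `metric="dice"`. Both map to [0,1], agree at 0 and 1, and are monotone
in the shared-target count; Jaccard is the default as the most common
set-overlap similarity for this use. Two empty target sets score 0.

**Disease semantic similarity.** Information content uses the natural
logarithm; the base only rescales IC and cancels in the SS ratio. The
semantic contribution `DV_S(t)` of ancestor `t` defaults to `IC(t)`
(model "ic"); the classical decay model (`DV_S(S)=1`,
`DV_S(t) = δ^k` with `k` the minimum tree-number segment distance and
δ = 0.5 by default) is provided as an alternative. The distance form equals
the usual max-over-children recursion when every intermediate level is
present and degrades gracefully when MeSH levels are unmapped. A disease
whose entire DAG has zero IC (e.g. only the root) has `DV = 0`; its
off-diagonal similarities are defined as 0 with a logged warning.

**Semantic + phenotypic combination.** For pairs where both diseases carry
OMIM numbers and a phenotypic score is available, the combined score is the
arithmetic mean `(SS+PS)/2` — the simplest symmetric combination mapping
[0,1]² to [0,1]; all other pairs keep `SS`.

MeSH ancestry is derived purely from tree-number prefixes (a term's parent
code is its code with the last dot-segment removed); multiple tree numbers
union their ancestor sets. Identifiers are whitespace-trimmed and
case-folded everywhere to prevent silent join failures across files.

## Flow computation

Capacities are integerized as `round(weight × 1000)` with banker's
rounding; arcs rounding to zero are dropped. The "infinite" source/sink
capacity is `1 + Σ(finite scaled capacities)` — a true effective infinity
for max flow, constructed after scaling. The solver is highest-label
push-relabel with the gap heuristic, on integers throughout, so results are
exact and free of float drift.

A maximum flow's value is unique but its arc decomposition is not, and the
default scoring ("single_flow") reads per-candidate scores off one flow
assignment. The implementation therefore fixes every source of order:
lexicographic node indexing, sorted arc insertion, highest-label selection
with a fixed stack discipline. The same graph always yields the same flow
assignment. A "per_candidate" mode is also provided in which each
candidate's score is the value of a dedicated max flow with only that
candidate attached to the sink — mathematically unique, at the cost of one
flow computation per candidate, and not equivalent in general: with a single
drain, flow may route *through* other candidates, so per-candidate scores
upper-bound the single-flow split.

Direction ablations: by default every undirected edge becomes two opposite
arcs; `direction_mode` can drop the miRNA→disease (or disease→miRNA) arcs
of association edges while similarity arcs stay bidirectional.

## Validation machinery

Each cross-validation fold removes association edge(s), rebuilds the
association layer — family/cluster ratios are recomputed without the
held-out edge, otherwise the deleted link would leak through the weights —
and ranks the held-out entity among candidates (every non-associated
entity by default, or a seeded random pool of stated size plus the held-out
one, drawn per fold). The ab initio variant removes *all* links of the
query before prioritizing.

**Rank-ratio orientation and ties.** Internally smaller rank ratio =
better, and a pair is predicted positive at cut `c` when its ratio is at
most `c`. Ranked-list output breaks score ties lexicographically for
reproducibility, but pooled CV statistics use midpoint percentile ranks,
`(average tied rank − 0.5)/n`: tied candidates share one ratio, and a fold
whose scores are all equal maps every candidate to exactly 0.5 regardless
of fold size. This makes a fully uninformative model (e.g. the
association-layer ablation, where no flow reaches any candidate) score ROC
AUC exactly 0.5 instead of inheriting an arbitrary alphabetical ordering.

ROC/PR curves sweep all distinct pooled rank ratios; AUC is trapezoidal,
so ROC AUC equals the tie-corrected Mann–Whitney statistic. PR AUC
integrates the best attainable precision at each distinct recall. Folds are
pooled into a single curve (per-query averaging is a possible alternative;
pooling weights each held-out association equally). The F1-optimal
threshold maximizes `2PR/(P+R)` over distinct cuts, ties going to the
smallest cut.

**Null models.** The association permutation redraws the bipartite edge
set uniformly at its original size (the stated constraint is only that the
link count is preserved; degree-preserving swaps would be a stricter null).
Similarity permutations shuffle the off-diagonal weights over the same
node-pair slots, preserving every thresholded edge count. Replicate `r`
uses seed `seed + r`.

Grid search evaluates the full Cartesian product, each axis ascending, first
maximum winning ties. Hypergeometric enrichment uses the exact upper tail
`P(X ≥ k)` computed in log space.

Ensembling averages rank ratios (scale-free) rather than raw scores, with
optional weights proportional to each method's AUC, normalized to sum 1.

## Synthetic benchmark

Defaults: 60 miRNAs, 40 diseases, 8 latent modules, within/between
association probabilities 0.3/0.01, within/between similarity means 0.6/0.1
with gaussian spread 0.1 (clipped, symmetrized, unit diagonal), 6 families
and 6 clusters of 3–6 within-module miRNAs, seed 1. These sizes give ~110
associations — large enough that pooled CV curves are stable and the full
validation suite (10-seed signal recovery plus a 10-replicate permutation
null) runs in well under a minute, while every flow problem stays ~100
nodes. Between-module pairs dominate, so with `sim_out` small the similarity
density is left-skewed, matching the qualitative shape observed on real
similarity networks.

What the benchmark does *not* emulate: real identifier vocabularies, the
heavy-tailed degree distribution of curated association databases,
correlated noise between the two similarity layers, and incompleteness
biases of target-prediction programs. Passing the validation suite on this
benchmark shows the machinery is correct and that planted signal of this
strength is recovered; it does not certify performance on any real corpus.

## Known limitations

- Single-flow scores, while deterministic, remain one of many optimal
  decompositions; rankings deep in the tail (score 0 candidates) are
  ordered lexicographically and carry no evidence.
- The semantic-similarity corpus is whatever disease universe is supplied;
  IC values change when the corpus changes.
- Grid search re-runs full CV per grid point and is exponential in the
  number of axes; the full 5-parameter grid from the original protocol
  (24 500 points) is feasible only on small benchmarks.
- OMIM phenotypic similarity is consumed as a precomputed matrix; no text
  mining is performed.
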