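"""Weighted rank-average ensembling of two predictors.

Combines two rank profiles over the same candidates; the combined score of
an item is the AUC-weighted mean of its rank ratios (smaller = better).
"""

from mirflow import RankProfile, rank_average

flow_model = RankProfile(
    "max_flow",
    {"mir-a": 0.2, "mir-b": 0.4, "mir-c": 0.6, "mir-d": 0.8, "mir-e": 1.0},
    weight=0.87,  # e.g. this method's cross-validation AUC
)
neighbour_model = RankProfile(
    "knn",
    {"mir-a": 0.4, "mir-b": 0.2, "mir-c": 1.0, "mir-d": 0.6, "mir-e": 0.8},
    weight=0.79,
)

combined = rank_average([flow_model, neighbour_model], weighted=True)
print("combined ranking (score = weighted mean rank ratio, smaller = better):")
for entry in combined.entries:
    print(f"  {entry.rank}  {entry.candidate_id}  score={entry.score:.3f}")
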