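"""Rank-average ensembling of multiple predictors' ranked lists.

Component methods score candidates on incommensurable scales, so the
combination operates on rank ratios: the ensemble score of an item is the
(weighted) mean of its rank ratios across methods, and a smaller combined
score is better. Weights, when used, are taken proportional to each
method's cross-validation AUC and normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import normalize_id
from .maxflow import RankedEntry, RankedList

__all__ = ["RankProfile", "rank_average"]


@dataclass(frozen=True)
class RankProfile:
    """One method's rank ratios over a common item set."""

    method_name: str
    rank_ratios: Mapping[str, float]
    weight: float | None = None

    @classmethod
    def from_ranked_list(
        cls, method_name: str, ranked: RankedList, weight: float | None = None
    ) -> "RankProfile":
        return cls(
            method_name=method_name,
            rank_ratios=ranked.rank_ratios(),
            weight=weight,
        )


def rank_average(
    profiles: Sequence[RankProfile], weighted: bool = False
) -> RankedList:
    """Combine >= 2 rank profiles by (weighted) mean rank ratio.

    All profiles must cover the identical item set. The combined list is
    ranked by ascending mean rank ratio with lexicographic tie-breaking;
    the stored score is the combined rank ratio itself (smaller = better).
    """
    if len(profiles) < 2:
        raise ValueError("rank averaging needs at least two profiles")
    items = {normalize_id(i) for i in profiles[0].rank_ratios}
    for profile in profiles[1:]:
        other = {normalize_id(i) for i in profile.rank_ratios}
        if other != items:
            diff = sorted(items.symmetric_difference(other))
            raise ValueError(
                f"profile {profile.method_name!r} covers a different item "
                f"set; symmetric difference: {diff}"
            )
    if weighted:
        weights = []
        for profile in profiles:
            if profile.weight is None or profile.weight < 0:
                raise ValueError(
                    f"profile {profile.method_name!r} lacks a usable weight"
                )
            weights.append(profile.weight)
        total = sum(weights)
        if total <= 0:
            raise ValueError("weights must have a positive sum")
        weights = [w / total for w in weights]
    else:
        weights = [1.0 / len(profiles)] * len(profiles)

    combined = {
        item: sum(
            w * profile.rank_ratios[item]
            for w, profile in zip(weights, profiles)
        )
        for item in items
    }
    ordered = sorted(combined.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(ordered)
    entries = tuple(
        RankedEntry(
            candidate_id=item,
            score=float(score),
            rank=rank,
            rank_ratio=rank / n,
        )
        for rank, (item, score) in enumerate(ordered, start=1)
    )
    return RankedList(entries=entries)
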