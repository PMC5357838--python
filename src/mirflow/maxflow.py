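"""Maximum information flow and flow-based candidate prioritization.

The solver is a highest-label push-relabel algorithm with the gap heuristic,
operating on integer capacities throughout (the network builder pre-scales
weights by 1000 and rounds, so flows are exact integers). Determinism is part
of the contract: nodes are indexed in lexicographic order, arcs are inserted
in sorted order, and active nodes are discharged highest-label-first with a
fixed stack discipline, so the same capacity graph always yields the same
flow assignment — not merely the same flow value. This matters because a
maximum flow is generally not unique and the per-candidate scores are read
off a single flow assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .netbuild import CapacityGraph, HeteroNetwork, ModelParams, directify

__all__ = [
    "FlowResult",
    "RankedEntry",
    "RankedList",
    "push_relabel_max_flow",
    "candidate_scores",
    "prioritize",
]


@dataclass(frozen=True)
class FlowResult:
    """A feasible maximum flow: per-arc integer flows and the total value."""

    arc_flow: Mapping[tuple[str, str], int]
    value: int


@dataclass(frozen=True)
class RankedEntry:
    candidate_id: str
    score: float
    rank: int
    rank_ratio: float


@dataclass(frozen=True)
class RankedList:
    """Candidates sorted by score (descending), ties broken by identifier.

    ``rank_ratio`` is rank / list length, so the best candidate has the
    smallest ratio.
    """

    entries: tuple[RankedEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def rank_of(self, candidate_id: str) -> int:
        for entry in self.entries:
            if entry.candidate_id == candidate_id:
                return entry.rank
        raise KeyError(candidate_id)

    def scores(self) -> dict[str, float]:
        return {e.candidate_id: e.score for e in self.entries}

    def rank_ratios(self) -> dict[str, float]:
        return {e.candidate_id: e.rank_ratio for e in self.entries}

    def midrank_ratios(self) -> dict[str, float]:
        """Midpoint percentile ranks: (average tied rank - 0.5) / length.

        This is the tie convention used when pooling cross-validation folds
        into ROC/PR curves: candidates the model cannot distinguish share
        one ratio instead of an arbitrary lexicographic split, and a list
        that is one big tie maps every candidate to exactly 0.5, so a fully
        uninformative fold contributes the same value whatever its size.
        """
        n = len(self.entries)
        out: dict[str, float] = {}
        i = 0
        while i < n:
            j = i
            while j < n and self.entries[j].score == self.entries[i].score:
                j += 1
            mid = (i + 1 + j) / 2.0 - 0.5  # average of ranks i+1 .. j, centred
            for k in range(i, j):
                out[self.entries[k].candidate_id] = mid / n
            i = j
        return out


def rank_candidates(scores: Mapping[str, float]) -> RankedList:
    """Sort candidate scores into a :class:`RankedList` (descending score,
    lexicographic tie-break)."""
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(ordered)
    entries = tuple(
        RankedEntry(
            candidate_id=cid,
            score=float(score),
            rank=rank,
            rank_ratio=rank / n,
        )
        for rank, (cid, score) in enumerate(ordered, start=1)
    )
    return RankedList(entries=entries)


def push_relabel_max_flow(graph: CapacityGraph) -> FlowResult:
    """Exact maximum flow from source to sink by highest-label push-relabel."""
    arc_nodes = {n for arc in graph.arcs for n in arc}
    if graph.source not in arc_nodes or graph.sink not in arc_nodes:
        raise ValueError("capacity graph must contain both source and sink")
    if graph.source == graph.sink:
        raise ValueError("source and sink must differ")
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    s, t = index[graph.source], index[graph.sink]

    # residual representation: edges added in pairs, eid ^ 1 is the reverse
    head: list[int] = []
    residual: list[int] = []
    adjacency: list[list[int]] = [[] for _ in range(n)]
    arc_order = sorted(graph.arcs)
    capacities: list[int] = []
    for u, v in arc_order:
        capacity = int(graph.arcs[(u, v)])
        if capacity < 0:
            raise ValueError(f"negative capacity on arc ({u}, {v})")
        ui, vi = index[u], index[v]
        adjacency[ui].append(len(head))
        head.append(vi)
        residual.append(capacity)
        adjacency[vi].append(len(head))
        head.append(ui)
        residual.append(0)
        capacities.append(capacity)

    height = [0] * n
    excess = [0] * n
    height[s] = n
    height_count = [0] * (2 * n + 1)
    for h in height:
        height_count[h] += 1

    buckets: list[list[int]] = [[] for _ in range(2 * n + 1)]
    current = [0] * n

    def activate(v: int) -> None:
        if v != s and v != t:
            buckets[height[v]].append(v)

    for eid in adjacency[s]:
        if eid % 2 == 0 and residual[eid] > 0:
            amount = residual[eid]
            residual[eid] = 0
            residual[eid ^ 1] += amount
            v = head[eid]
            excess[v] += amount
            excess[s] -= amount
            activate(v)

    highest = 0

    def lift(u: int) -> None:
        old = height[u]
        lowest: int | None = None
        for eid in adjacency[u]:
            if residual[eid] > 0:
                h = height[head[eid]]
                if lowest is None or h < lowest:
                    lowest = h
        # a node with excess always has a residual arc (the one its excess
        # arrived through), so ``lowest`` is never None here
        height[u] = (lowest + 1) if lowest is not None else 2 * n
        height_count[old] -= 1
        height_count[height[u]] += 1
        if height_count[old] == 0 and old < n:
            # gap heuristic: nodes stranded above an empty height can never
            # reach the sink again; lift them past n in one step
            for v in range(n):
                if v != s and old < height[v] < n:
                    height_count[height[v]] -= 1
                    height[v] = n + 1
                    height_count[height[v]] += 1
                    current[v] = 0

    while highest >= 0:
        if not buckets[highest]:
            highest -= 1
            continue
        u = buckets[highest].pop()
        if u == s or u == t or excess[u] == 0 or height[u] != highest:
            continue
        # discharge u to completion
        while excess[u] > 0:
            if current[u] == len(adjacency[u]):
                lift(u)
                current[u] = 0
                continue
            eid = adjacency[u][current[u]]
            v = head[eid]
            if residual[eid] > 0 and height[u] == height[v] + 1:
                amount = min(excess[u], residual[eid])
                residual[eid] -= amount
                residual[eid ^ 1] += amount
                excess[u] -= amount
                if excess[v] == 0:
                    activate(v)
                excess[v] += amount
            else:
                current[u] += 1
        if height[u] > highest:
            highest = min(height[u], 2 * n)

    arc_flow = {
        arc: capacities[i] - residual[2 * i] for i, arc in enumerate(arc_order)
    }
    return FlowResult(arc_flow=arc_flow, value=int(excess[t]))


def candidate_scores(
    flow: FlowResult,
    graph: CapacityGraph,
    score_mode: str = "single_flow",
) -> RankedList:
    """Read per-candidate association scores off a maximum flow.

    "single_flow": the score of candidate u is the flow on the arc (u, sink)
    in the one supplied maximum flow (all source-to-sink flow exits through
    these arcs, so the scores sum to the flow value). "per_candidate": the
    score of u is the value of a dedicated maximum flow in which only u is
    attached to the sink; slower by a factor of the candidate count, but
    independent of how the single flow happens to decompose.
    """
    if score_mode == "single_flow":
        scores = {
            c: float(flow.arc_flow.get((c, graph.sink), 0))
            for c in graph.candidates
        }
    elif score_mode == "per_candidate":
        scores = {}
        for candidate in graph.candidates:
            arcs = {
                arc: cap
                for arc, cap in graph.arcs.items()
                if arc[1] != graph.sink or arc[0] == candidate
            }
            sub = CapacityGraph(
                arcs=arcs,
                query=graph.query,
                candidates=(candidate,),
                infinity_value=graph.infinity_value,
                source=graph.source,
                sink=graph.sink,
            )
            scores[candidate] = float(push_relabel_max_flow(sub).value)
    else:
        raise ValueError(f"unknown score_mode: {score_mode!r}")
    return rank_candidates(scores)


def prioritize(
    network: HeteroNetwork,
    query_id: str,
    candidate_ids: Sequence[str],
    params: ModelParams,
    score_mode: str = "single_flow",
) -> RankedList:
    """Rank candidates for a query by maximum information flow.

    Works symmetrically for both directions of inference: with a disease
    query the candidates are miRNAs, with a miRNA query they are diseases.
    """
    graph = directify(network, query_id, candidate_ids, params)
    flow = push_relabel_max_flow(graph)
    return candidate_scores(flow, graph, score_mode=score_mode)
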