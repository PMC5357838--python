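"""Assembly of the microRNAome-phenome network and its flow-network form.

The undirected heterogeneous network UG has three edge layers: miRNA-miRNA
functional similarity (kept when similarity >= alpha), disease-disease
semantic/phenotypic similarity (kept when >= beta), and miRNA-disease
association edges. Association edges carry a base capacity gamma, inflated
for miRNAs whose family or genomic cluster is already enriched for the
disease: a family with a fraction R_p of its members linked to the disease
contributes a factor (1 + eta * R_p), a cluster analogously with sigma.

For a query, UG is turned into a directed integer-capacity graph DG: each
undirected edge splits into two opposite arcs with capacity
round(weight * capacity_scale), an artificial source feeds the query and an
artificial sink drains every candidate through effectively infinite arcs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import AssociationTable, GeneSetCollection, SimilarityMatrix, normalize_id

__all__ = [
    "ModelParams",
    "HeteroNetwork",
    "CapacityGraph",
    "SOURCE",
    "SINK",
    "family_cluster_ratio",
    "association_edge_weight",
    "association_layer_edges",
    "assemble_network",
    "directify",
]

logger = logging.getLogger(__name__)

SOURCE = "__source__"
SINK = "__sink__"

LAYERS = ("mirna_sim", "disease_sim", "association")
DIRECTION_MODES = ("both", "disease_to_mirna_only", "mirna_to_disease_only")


@dataclass(frozen=True)
class ModelParams:
    """Tunable parameters of the flow model.

    alpha/beta are the similarity thresholds for the miRNA and disease
    layers; gamma is the base association capacity; eta and sigma scale the
    family and cluster corrections; capacity_scale is the integerization
    factor applied to every finite weight.
    """

    alpha: float = 0.1
    beta: float = 0.6
    gamma: float = 100.0
    eta: float = 6.0
    sigma: float = 10.0
    capacity_scale: int = 1000
    direction_mode: str = "both"
    tie_break: str = "lexicographic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.gamma <= 0 or self.capacity_scale <= 0:
            raise ValueError("gamma and capacity_scale must be positive")
        if self.eta < 0 or self.sigma < 0:
            raise ValueError("eta and sigma must be non-negative")
        if self.direction_mode not in DIRECTION_MODES:
            raise ValueError(f"unknown direction_mode: {self.direction_mode!r}")
        if self.tie_break != "lexicographic":
            raise ValueError("only lexicographic tie-breaking is supported")


@dataclass(frozen=True)
class HeteroNetwork:
    """Undirected weighted microRNAome-phenome graph UG = (V, E).

    ``node_kinds`` maps every node to "mirna" or "disease"; ``edges`` maps an
    unordered pair (stored sorted) to (weight, layer).
    """

    node_kinds: Mapping[str, str]
    edges: Mapping[tuple[str, str], tuple[float, str]]

    def edges_in_layer(self, layer: str) -> dict[tuple[str, str], float]:
        return {e: w for e, (w, l) in self.edges.items() if l == layer}

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out

    def __contains__(self, node: str) -> bool:
        return node in self.node_kinds


@dataclass(frozen=True)
class CapacityGraph:
    """Directed integer-capacity flow network DG for one query.

    ``arcs`` maps (u, v) to a non-negative integer capacity. The source
    feeds only the query; every candidate drains into the sink through an
    arc of capacity ``infinity_value``, which strictly exceeds the sum of
    all finite capacities.
    """

    arcs: Mapping[tuple[str, str], int]
    query: str
    candidates: tuple[str, ...]
    infinity_value: int
    source: str = SOURCE
    sink: str = SINK

    @property
    def nodes(self) -> set[str]:
        out = {self.source, self.sink}
        for u, v in self.arcs:
            out.add(u)
            out.add(v)
        return out


def family_cluster_ratio(
    group_members: Iterable[str], disease_id: str, assoc: AssociationTable
) -> float:
    """Fraction of the group's miRNAs already associated with the disease."""
    members = [normalize_id(m) for m in group_members]
    if not members:
        raise ValueError("family/cluster group must be nonempty")
    associated = assoc.associated_mirnas(normalize_id(disease_id))
    return sum(m in associated for m in members) / len(members)


def _best_group_ratio(
    mirna: str, disease: str, groups: GeneSetCollection, assoc: AssociationTable
) -> float:
    """Highest co-association ratio over every group containing the miRNA."""
    best = 0.0
    for name in groups.sets_containing(mirna):
        ratio = family_cluster_ratio(groups.members(name), disease, assoc)
        best = max(best, ratio)
    return best


def association_edge_weight(
    mirna: str,
    disease: str,
    families: GeneSetCollection,
    clusters: GeneSetCollection,
    assoc: AssociationTable,
    params: ModelParams,
) -> float:
    """Capacity of one association edge: gamma * (1 + eta*R_p + sigma*R_q).

    R_p (R_q) is the co-association ratio of the best family (cluster)
    containing the miRNA; a miRNA in no enriched group keeps the base gamma.
    """
    mirna, disease = normalize_id(mirna), normalize_id(disease)
    if (mirna, disease) not in assoc.pairs:
        raise KeyError(f"({mirna}, {disease}) is not a known association")
    r_family = _best_group_ratio(mirna, disease, families, assoc)
    r_cluster = _best_group_ratio(mirna, disease, clusters, assoc)
    return params.gamma * (1.0 + params.eta * r_family + params.sigma * r_cluster)


def association_layer_edges(
    assoc: AssociationTable,
    families: GeneSetCollection,
    clusters: GeneSetCollection,
    params: ModelParams,
) -> dict[tuple[str, str], tuple[float, str]]:
    """Weighted association edges for a whole table in one pass.

    Equivalent to calling :func:`association_edge_weight` per record, but the
    per-disease association sets are indexed once, which matters inside
    cross-validation where this layer is rebuilt for every fold.
    """
    by_disease: dict[str, set[str]] = {}
    for mirna, disease in assoc.records:
        by_disease.setdefault(disease, set()).add(mirna)
    member_sets: dict[str, frozenset[str]] = {}
    for groups in (families, clusters):
        for name, members in groups.sets.items():
            member_sets.setdefault(name, frozenset(members))

    edges: dict[tuple[str, str], tuple[float, str]] = {}
    for mirna, disease in assoc.records:
        associated = by_disease[disease]
        r_family = 0.0
        for name in families.sets_containing(mirna):
            members = member_sets[name]
            r_family = max(r_family, len(members & associated) / len(members))
        r_cluster = 0.0
        for name in clusters.sets_containing(mirna):
            members = member_sets[name]
            r_cluster = max(r_cluster, len(members & associated) / len(members))
        weight = params.gamma * (
            1.0 + params.eta * r_family + params.sigma * r_cluster
        )
        u, v = sorted((mirna, disease))
        edges[(u, v)] = (weight, "association")
    return edges


def assemble_network(
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    assoc: AssociationTable,
    families: GeneSetCollection,
    clusters: GeneSetCollection,
    params: ModelParams,
) -> HeteroNetwork:
    """Build UG from the two similarity layers and the association layer.

    Similarity edges are kept when the score meets the layer threshold
    (alpha for miRNAs, beta for diseases); association edges are weighted by
    :func:`association_edge_weight`. Nodes missing from a similarity matrix
    are retained as association-only nodes with a warning.
    """
    node_kinds: dict[str, str] = {}
    for label in mirna_sim.labels:
        node_kinds[label] = "mirna"
    for label in disease_sim.labels:
        if label in node_kinds:
            raise ValueError(f"label {label!r} appears in both similarity layers")
        node_kinds[label] = "disease"
    for mirna, disease in assoc.records:
        if mirna not in mirna_sim:
            logger.warning("miRNA %s missing from similarity matrix", mirna)
        if disease not in disease_sim:
            logger.warning("disease %s missing from similarity matrix", disease)
        node_kinds.setdefault(mirna, "mirna")
        node_kinds.setdefault(disease, "disease")

    edges: dict[tuple[str, str], tuple[float, str]] = {}

    def add_similarity_layer(
        matrix: SimilarityMatrix, threshold: float, layer: str
    ) -> None:
        keep = np.argwhere(np.triu(matrix.values >= threshold, k=1))
        for i, j in keep:
            weight = float(matrix.values[i, j])
            if weight <= 0.0:
                continue
            u, v = sorted((matrix.labels[i], matrix.labels[j]))
            edges[(u, v)] = (weight, layer)

    add_similarity_layer(mirna_sim, params.alpha, "mirna_sim")
    add_similarity_layer(disease_sim, params.beta, "disease_sim")

    edges.update(association_layer_edges(assoc, families, clusters, params))

    return HeteroNetwork(node_kinds=node_kinds, edges=edges)


def directify(
    network: HeteroNetwork,
    query_id: str,
    candidate_ids: Sequence[str],
    params: ModelParams,
) -> CapacityGraph:
    """Turn UG into the directed integer-capacity flow network for a query.

    Every undirected edge becomes two opposite arcs of capacity
    round(weight * capacity_scale) (banker's rounding; zero-capacity arcs are
    dropped). Under a one-directional mode the association arcs against the
    allowed direction are removed; similarity arcs stay bidirectional. The
    source->query and candidate->sink arcs get 1 + (sum of finite
    capacities), a true effective infinity.
    """
    query = normalize_id(query_id)
    candidates = tuple(sorted({normalize_id(c) for c in candidate_ids}))
    if query not in network:
        raise KeyError(f"query node {query!r} is not in the network")
    if not candidates:
        raise ValueError("candidate set must be nonempty")
    if query in candidates:
        raise ValueError("query must not appear among the candidates")

    arcs: dict[tuple[str, str], int] = {}
    total = 0
    for (u, v), (weight, layer) in network.edges.items():
        capacity = round(weight * params.capacity_scale)
        if capacity <= 0:
            continue
        forward = backward = True
        if layer == "association":
            mirna, disease = (
                (u, v) if network.node_kinds[u] == "mirna" else (v, u)
            )
            if params.direction_mode == "disease_to_mirna_only":
                # drop the arc running mirna -> disease
                if (u, v) == (mirna, disease):
                    forward = False
                else:
                    backward = False
            elif params.direction_mode == "mirna_to_disease_only":
                if (u, v) == (disease, mirna):
                    forward = False
                else:
                    backward = False
        if forward:
            arcs[(u, v)] = capacity
            total += capacity
        if backward:
            arcs[(v, u)] = capacity
            total += capacity

    infinity_value = 1 + total
    arcs[(SOURCE, query)] = infinity_value
    for candidate in candidates:
        arcs[(candidate, SINK)] = infinity_value

    return CapacityGraph(
        arcs=arcs,
        query=query,
        candidates=candidates,
        infinity_value=infinity_value,
    )
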