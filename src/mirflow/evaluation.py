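"""Validation machinery for the flow-based prioritizer.

Every experiment reduces a prioritization to rank ratios: the rank of an item
divided by the number of ranked candidates, so a perfectly recovered held-out
association sits near 0 and a useless one near 1. Smaller rank ratio is
better throughout; a pair is "predicted positive" at a cut c when its ratio
is at most c. Pooled rank ratios use midranks for tied scores, so a model
that cannot distinguish its candidates is scored as exactly uninformative
(ROC AUC 0.5) rather than rewarded or punished by the lexicographic output
order.

Provided experiments: leave-one-out cross-validation, ab initio
cross-validation (all of the query's links removed), layer-permutation null
models, single-layer ablations, exhaustive parameter grid search, and the
hypergeometric enrichment test used to judge prediction/database overlap.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import precision_recall_curve, roc_curve

from .io import AssociationTable, GeneSetCollection, SimilarityMatrix
from .maxflow import prioritize
from .netbuild import (
    HeteroNetwork,
    ModelParams,
    assemble_network,
    association_layer_edges,
)

__all__ = [
    "EvalCurve",
    "FoldRecord",
    "CvResult",
    "roc_pr_from_ranks",
    "f1_optimal_threshold",
    "loocv",
    "ab_initio_cv",
    "permutation_experiment",
    "permute_layer",
    "ablation",
    "grid_search",
    "hypergeometric_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalCurve:
    """One performance curve (ROC or PR) over rank-ratio thresholds.

    ``thresholds`` are rank-ratio cut points; ``points`` holds (x, y) pairs
    (FPR/TPR for ROC, Recall/Precision for PR); ``auc`` is the trapezoidal
    area.
    """

    thresholds: np.ndarray
    points: np.ndarray
    auc: float

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class FoldRecord:
    query_id: str
    held_out_id: str
    rank: int
    rank_ratio: float
    n_candidates: int


@dataclass(frozen=True)
class CvResult:
    """Pooled outcome of one cross-validation experiment."""

    folds: tuple[FoldRecord, ...]
    positives: np.ndarray
    negatives: np.ndarray
    roc: EvalCurve
    pr: EvalCurve
    params: ModelParams

    @property
    def auc(self) -> float:
        return self.roc.auc


def roc_pr_from_ranks(
    positives: Sequence[float], negatives: Sequence[float]
) -> tuple[EvalCurve, EvalCurve]:
    """ROC and PR curves from pooled positive/negative rank ratios.

    The threshold sweeps every distinct rank ratio; smaller ratios are
    better. ROC AUC by the trapezoidal rule equals the normalized
    Mann-Whitney statistic (ties counted half).
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative rank ratio")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    scores = -np.concatenate([pos, neg])  # larger score = better

    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    roc_auc = float(np.trapezoid(tpr, fpr))
    roc = EvalCurve(
        thresholds=-thr,  # back onto the rank-ratio scale
        points=np.column_stack([fpr, tpr]),
        auc=roc_auc,
    )

    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    # one point per distinct recall, keeping the best attainable precision
    unique_recall = np.unique(recall)
    best_precision = np.array(
        [precision[recall == r].max() for r in unique_recall]
    )
    pr_auc = float(np.trapezoid(best_precision, unique_recall))
    pr = EvalCurve(
        thresholds=-pr_thr,
        points=np.column_stack([recall, precision]),
        auc=pr_auc,
    )
    return roc, pr


def f1_optimal_threshold(
    positives: Sequence[float], negatives: Sequence[float]
) -> tuple[float, float]:
    """The rank-ratio cut maximizing F1, and the F1 value reached there.

    Predictions at cut c are the pairs with rank ratio <= c; ties in F1 go to
    the smallest cut.
    """
    pos = np.sort(np.asarray(positives, dtype=float))
    neg = np.sort(np.asarray(negatives, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative rank ratio")
    cuts = np.unique(np.concatenate([pos, neg]))
    best_cut, best_f1 = float(cuts[0]), -1.0
    for cut in cuts:
        tp = int(np.searchsorted(pos, cut, side="right"))
        fp = int(np.searchsorted(neg, cut, side="right"))
        if tp == 0:
            f1 = 0.0
        else:
            precision = tp / (tp + fp)
            recall = tp / pos.size
            f1 = 2 * precision * recall / (precision + recall)
        if f1 > best_f1:
            best_cut, best_f1 = float(cut), float(f1)
    return best_cut, best_f1


# ---------------------------------------------------------------------------
# cross-validation engine
# ---------------------------------------------------------------------------


def _entity_universes(
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    assoc: AssociationTable,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    mirnas = tuple(dict.fromkeys([*mirna_sim.labels, *assoc.mirnas]))
    diseases = tuple(dict.fromkeys([*disease_sim.labels, *assoc.diseases]))
    return mirnas, diseases


def _similarity_edges(
    network: HeteroNetwork,
) -> dict[tuple[str, str], tuple[float, str]]:
    return {
        e: wl for e, wl in network.edges.items() if wl[1] != "association"
    }


def _run_cv(
    assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    families: GeneSetCollection,
    clusters: GeneSetCollection,
    params: ModelParams,
    mode: str,
    candidate_pool: str | int,
    seed: int,
    score_mode: str,
    ab_initio: bool,
    drop_layer: str | None = None,
) -> CvResult:
    if mode not in ("mirna", "disease"):
        raise ValueError(f"unknown prioritization mode: {mode!r}")
    if len(assoc) == 0:
        raise ValueError("association table is empty")

    base = assemble_network(
        mirna_sim, disease_sim, assoc, families, clusters, params
    )
    sim_edges = _similarity_edges(base)
    if drop_layer in ("mirna_sim", "disease_sim"):
        sim_edges = {e: wl for e, wl in sim_edges.items() if wl[1] != drop_layer}
    node_kinds = base.node_kinds
    mirna_universe, disease_universe = _entity_universes(
        mirna_sim, disease_sim, assoc
    )

    rng = np.random.default_rng(seed)
    folds: list[FoldRecord] = []
    positives: list[float] = []
    negatives: list[float] = []

    for mirna, disease in assoc.records:
        if mode == "mirna":
            query, held_out = disease, mirna
            universe = mirna_universe
            known = assoc.associated_mirnas(disease)
        else:
            query, held_out = mirna, disease
            universe = disease_universe
            known = assoc.associated_diseases(mirna)

        if ab_initio:
            removed = (
                [(m, disease) for m in known]
                if mode == "mirna"
                else [(mirna, d) for d in known]
            )
        else:
            removed = [(mirna, disease)]
        assoc_fold = assoc.without(removed)

        non_associated = [
            e for e in universe if e not in known and e != query
        ]
        if candidate_pool == "all":
            candidates = sorted({*non_associated, held_out})
        else:
            pool_size = int(candidate_pool)
            others = [e for e in non_associated if e != held_out]
            if pool_size > len(others):
                raise ValueError(
                    f"candidate pool {pool_size} exceeds the "
                    f"{len(others)} available non-associated entities"
                )
            drawn = rng.choice(len(others), size=pool_size, replace=False)
            candidates = sorted({held_out, *(others[i] for i in drawn)})

        edges = dict(sim_edges)
        if drop_layer != "associations":
            edges.update(
                association_layer_edges(assoc_fold, families, clusters, params)
            )
        network = HeteroNetwork(node_kinds=node_kinds, edges=edges)
        ranked = prioritize(network, query, candidates, params, score_mode)
        mid = ranked.midrank_ratios()
        folds.append(
            FoldRecord(
                query_id=query,
                held_out_id=held_out,
                rank=ranked.rank_of(held_out),
                rank_ratio=mid[held_out],
                n_candidates=len(candidates),
            )
        )
        positives.append(mid[held_out])
        negatives.extend(mid[c] for c in candidates if c != held_out)

    roc, pr = roc_pr_from_ranks(positives, negatives)
    return CvResult(
        folds=tuple(folds),
        positives=np.asarray(positives),
        negatives=np.asarray(negatives),
        roc=roc,
        pr=pr,
        params=params,
    )


def loocv(
    assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    families: GeneSetCollection,
    clusters: GeneSetCollection,
    params: ModelParams,
    mode: str = "mirna",
    candidate_pool: str | int = "all",
    seed: int = 0,
    score_mode: str = "single_flow",
) -> CvResult:
    """Leave-one-out cross-validation over every known association.

    For each association the corresponding edge is removed, the association
    layer (including family/cluster ratios) is rebuilt without it, and the
    held-out entity is prioritized against the candidates (every
    non-associated entity, or a seeded random pool of the given size plus
    the held-out one).
    """
    return _run_cv(
        assoc, mirna_sim, disease_sim, families, clusters, params,
        mode, candidate_pool, seed, score_mode, ab_initio=False,
    )


def ab_initio_cv(
    assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    families: GeneSetCollection,
    clusters: GeneSetCollection,
    params: ModelParams,
    mode: str = "mirna",
    candidate_pool: str | int = "all",
    seed: int = 0,
    score_mode: str = "single_flow",
) -> CvResult:
    """Cross-validation for queries stripped of every known association.

    Like :func:`loocv`, but all of the query's association edges are removed
    before prioritizing, emulating a query entity with no annotations at
    all. One fold per (query, held-out) pair.
    """
    return _run_cv(
        assoc, mirna_sim, disease_sim, families, clusters, params,
        mode, candidate_pool, seed, score_mode, ab_initio=True,
    )


# ---------------------------------------------------------------------------
# null models, ablations, grids
# ---------------------------------------------------------------------------


def permute_layer(
    layer: str,
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    assoc: AssociationTable,
    rng: np.random.Generator,
) -> tuple[SimilarityMatrix, SimilarityMatrix, AssociationTable]:
    """One shuffled copy of the named layer, edge counts preserved exactly.

    "associations": the bipartite edge set is redrawn uniformly at its
    original size over the miRNA x disease universe. Similarity layers:
    the off-diagonal weights are permuted over the same node-pair slots.
    """
    if layer == "associations":
        mirnas, diseases = _entity_universes(mirna_sim, disease_sim, assoc)
        n_cells = len(mirnas) * len(diseases)
        if len(assoc) > n_cells:
            raise ValueError("more associations than miRNA-disease pairs")
        chosen = rng.choice(n_cells, size=len(assoc), replace=False)
        records = tuple(
            (mirnas[c // len(diseases)], diseases[c % len(diseases)])
            for c in sorted(chosen)
        )
        return mirna_sim, disease_sim, AssociationTable(records=records)
    if layer in ("mirna_sim", "disease_sim"):
        matrix = mirna_sim if layer == "mirna_sim" else disease_sim
        values = matrix.values.copy()
        iu = np.triu_indices(len(matrix.labels), k=1)
        shuffled = values[iu][rng.permutation(iu[0].size)]
        values[iu] = shuffled
        values.T[iu] = shuffled
        permuted = SimilarityMatrix(labels=matrix.labels, values=values)
        if layer == "mirna_sim":
            return permuted, disease_sim, assoc
        return mirna_sim, permuted, assoc
    raise ValueError(f"unknown layer: {layer!r}")


def permutation_experiment(
    assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    families: GeneSetCollection,
    clusters: GeneSetCollection,
    params: ModelParams,
    layer: str = "associations",
    n_reps: int = 10,
    seed: int = 1,
    mode: str = "mirna",
    candidate_pool: str | int = "all",
    score_mode: str = "single_flow",
) -> list[float]:
    """LOOCV AUCs on replicates with one network layer shuffled.

    Replicate r uses seed ``seed + r``; with genuine signal in the intact
    network these null AUCs concentrate around 0.5.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    aucs: list[float] = []
    for rep in range(n_reps):
        rep_seed = seed + rep
        rng = np.random.default_rng(rep_seed)
        m_sim, d_sim, a = permute_layer(layer, mirna_sim, disease_sim, assoc, rng)
        result = loocv(
            a, m_sim, d_sim, families, clusters, params,
            mode=mode, candidate_pool=candidate_pool,
            seed=rep_seed, score_mode=score_mode,
        )
        logger.info("permutation rep %d (%s): AUC=%.4f", rep, layer, result.auc)
        aucs.append(result.auc)
    return aucs


def ablation(
    assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    families: GeneSetCollection,
    clusters: GeneSetCollection,
    params: ModelParams,
    drop: str = "mirna_sim",
    mode: str = "mirna",
    candidate_pool: str | int = "all",
    seed: int = 0,
    score_mode: str = "single_flow",
) -> CvResult:
    """LOOCV with one edge layer removed from the network entirely."""
    if drop not in ("mirna_sim", "disease_sim", "associations"):
        raise ValueError(f"unknown layer: {drop!r}")
    return _run_cv(
        assoc, mirna_sim, disease_sim, families, clusters, params,
        mode, candidate_pool, seed, score_mode,
        ab_initio=False, drop_layer=drop,
    )


def grid_search(
    assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    families: GeneSetCollection,
    clusters: GeneSetCollection,
    grid: Mapping[str, Sequence[float]],
    base_params: ModelParams | None = None,
    mode: str = "mirna",
    cv: str = "loocv",
    candidate_pool: str | int = "all",
    seed: int = 0,
) -> tuple[ModelParams, pd.DataFrame]:
    """Exhaustive AUC evaluation over a Cartesian parameter grid.

    ``grid`` maps parameter names (alpha, beta, gamma, eta, sigma, ...) to
    candidate values; each axis is iterated in ascending order and the first
    maximal-AUC combination wins ties. Returns the winning parameters and
    the full AUC table.
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    if cv not in ("loocv", "abinitio"):
        raise ValueError(f"unknown cv scheme: {cv!r}")
    base = base_params if base_params is not None else ModelParams()
    names = sorted(grid)
    axes = [sorted(grid[name]) for name in names]
    runner = loocv if cv == "loocv" else ab_initio_cv

    rows = []
    best_auc, best_params = -np.inf, base
    for combo in itertools.product(*axes):
        params = replace(base, **dict(zip(names, combo)))
        result = runner(
            assoc, mirna_sim, disease_sim, families, clusters, params,
            mode=mode, candidate_pool=candidate_pool, seed=seed,
        )
        rows.append({**dict(zip(names, combo)), "auc": result.auc})
        if result.auc > best_auc:
            best_auc, best_params = result.auc, params
    return best_params, pd.DataFrame(rows)


def hypergeometric_enrichment(
    overlap: int, predicted: int, annotated: int, universe: int
) -> float:
    """Upper-tail probability of seeing >= ``overlap`` annotated items among
    ``predicted`` draws from a universe containing ``annotated`` annotated
    items (computed in log space)."""
    k, n, big_k, big_n = overlap, predicted, annotated, universe
    if not (0 <= k <= min(n, big_k) <= big_n) or n > big_n or big_k > big_n:
        raise ValueError(
            f"inconsistent counts: overlap={k}, predicted={n}, "
            f"annotated={big_k}, universe={big_n}"
        )
    if k == 0:
        return 1.0
    return float(np.exp(hypergeom.logsf(k - 1, big_n, big_k, n)))
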