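"""MicroRNA functional similarity and disease semantic/phenotypic similarity.

MicroRNA similarity is computed from predicted target-gene sets as a set
overlap (Jaccard by default, Dice optionally). Disease similarity follows the
information-content view of the MeSH disease hierarchy: a term appearing in
few disease DAGs is informative, and two diseases are similar in proportion to
the semantic weight of the ancestors they share. Where a text-mined phenotypic
similarity is available for an OMIM-mapped disease pair, it is averaged with
the semantic score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GeneSetCollection, MeshDag, SimilarityMatrix, normalize_id

__all__ = [
    "SemanticProfile",
    "IcTable",
    "target_overlap_similarity",
    "build_mirna_similarity",
    "information_content",
    "build_ic_table",
    "semantic_profile",
    "semantic_similarity",
    "build_disease_semantic_similarity",
    "combine_semantic_phenotypic",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SemanticProfile:
    """Per-ancestor semantic contributions of one disease.

    ``contributions`` is keyed exactly by ``dag(disease)`` (ancestors
    including the disease itself); ``dv_total`` is the semantic value DV,
    the sum of all contributions.
    """

    disease_id: str
    contributions: Mapping[str, float]
    dv_total: float


@dataclass(frozen=True)
class IcTable:
    """Information content per disease term over a corpus of disease DAGs.

    IC(t) = -ln of the fraction of corpus DAGs containing t; a term present
    in every DAG carries no information (IC = 0).
    """

    ic: Mapping[str, float]
    corpus_size: int

    def __getitem__(self, term: str) -> float:
        return self.ic[normalize_id(term)]

    def __contains__(self, term: str) -> bool:
        return normalize_id(term) in self.ic


def target_overlap_similarity(
    targets_i: Iterable[str],
    targets_j: Iterable[str],
    metric: str = "jaccard",
) -> float:
    """Set-overlap similarity of two target-gene sets, in [0, 1].

    With ``n_com`` shared targets out of ``n_i`` and ``n_j``:
    jaccard = n_com / (n_i + n_j - n_com); dice = 2 n_com / (n_i + n_j).
    Two empty sets score 0.
    """
    set_i, set_j = set(targets_i), set(targets_j)
    n_com = len(set_i & set_j)
    n_i, n_j = len(set_i), len(set_j)
    if n_i + n_j == 0:
        return 0.0
    if metric == "jaccard":
        return n_com / (n_i + n_j - n_com)
    if metric == "dice":
        return 2.0 * n_com / (n_i + n_j)
    raise ValueError(f"unknown overlap metric: {metric!r}")


def build_mirna_similarity(
    targets: GeneSetCollection,
    mirnas: Sequence[str],
    metric: str = "jaccard",
) -> SimilarityMatrix:
    """Pairwise target-overlap similarity matrix over the listed miRNAs."""
    labels = [normalize_id(m) for m in mirnas]
    missing = [m for m in labels if m not in targets.sets]
    if missing:
        raise KeyError(f"miRNAs absent from target sets: {missing}")
    sets = [set(targets.sets[m]) for m in labels]
    n = len(labels)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = target_overlap_similarity(
                sets[i], sets[j], metric=metric
            )
    return SimilarityMatrix(labels=labels, values=values)


def build_ic_table(dag: MeshDag, universe: Iterable[str] | None = None) -> IcTable:
    """Information content of every term occurring in the corpus DAGs.

    ``universe`` is the set of diseases whose DAGs form the corpus; it
    defaults to every term in ``dag``.
    """
    diseases = sorted(
        normalize_id(d) for d in (universe if universe is not None else dag.terms)
    )
    if not diseases:
        raise ValueError("empty disease corpus")
    counts: dict[str, int] = {}
    for disease in diseases:
        for term in dag.dag(disease):
            counts[term] = counts.get(term, 0) + 1
    size = len(diseases)
    ic = {term: -math.log(count / size) for term, count in counts.items()}
    return IcTable(ic=ic, corpus_size=size)


def information_content(
    term: str, dag: MeshDag, universe: Iterable[str] | None = None
) -> float:
    """IC of one term: -ln(fraction of corpus disease DAGs containing it)."""
    table = build_ic_table(dag, universe)
    term = normalize_id(term)
    if term not in table:
        raise KeyError(f"term {term!r} appears in no disease DAG; IC undefined")
    return table[term]


def _min_segment_distance(dag: MeshDag, disease: str, ancestor: str) -> int:
    """Minimum tree-number segment distance from disease down to ancestor."""
    best: int | None = None
    ancestor_numbers = dag.terms[ancestor]
    for tn in dag.terms[disease]:
        segments = tn.split(".")
        for k in range(len(segments), 0, -1):
            prefix = ".".join(segments[:k])
            if prefix in ancestor_numbers:
                dist = len(segments) - k
                best = dist if best is None else min(best, dist)
    if best is None:
        raise ValueError(f"{ancestor!r} is not a tree-number ancestor of {disease!r}")
    return best


def semantic_profile(
    disease: str,
    dag: MeshDag,
    ic: IcTable,
    model: str = "ic",
    delta: float = 0.5,
) -> SemanticProfile:
    """Semantic contributions of every ancestor of ``disease``.

    model "ic": each ancestor t contributes IC(t). model "decay": the disease
    itself contributes 1 and each ancestor contributes delta**k where k is its
    minimum tree-number segment distance from the disease (the classical
    hierarchy-decay semantic value).
    """
    disease = normalize_id(disease)
    ancestors = dag.dag(disease)
    if model == "ic":
        contributions = {t: ic[t] for t in ancestors}
    elif model == "decay":
        contributions = {}
        for t in ancestors:
            if t == disease:
                contributions[t] = 1.0
            else:
                contributions[t] = delta ** _min_segment_distance(dag, disease, t)
    else:
        raise ValueError(f"unknown semantic model: {model!r}")
    return SemanticProfile(
        disease_id=disease,
        contributions=contributions,
        dv_total=float(sum(contributions.values())),
    )


def semantic_similarity(a: SemanticProfile, b: SemanticProfile) -> float:
    """Shared-ancestor similarity SS(A,B) in [0, 1].

    SS = sum over shared ancestors t of (DV_A(t) + DV_B(t)), divided by
    DV(A) + DV(B). Degenerate zero-total profiles score 0 (with a warning)
    off-diagonal and 1 for a disease against itself.
    """
    if a.disease_id == b.disease_id:
        return 1.0
    denominator = a.dv_total + b.dv_total
    if denominator == 0.0:
        logger.warning(
            "both %s and %s have zero semantic value; similarity set to 0",
            a.disease_id,
            b.disease_id,
        )
        return 0.0
    shared = a.contributions.keys() & b.contributions.keys()
    numerator = sum(a.contributions[t] + b.contributions[t] for t in shared)
    return float(numerator / denominator)


def build_disease_semantic_similarity(
    dag: MeshDag,
    diseases: Sequence[str] | None = None,
    model: str = "ic",
    delta: float = 0.5,
) -> SimilarityMatrix:
    """Pairwise semantic similarity over the disease corpus."""
    labels = sorted(
        normalize_id(d) for d in (diseases if diseases is not None else dag.terms)
    )
    ic = build_ic_table(dag, labels)
    profiles = [semantic_profile(d, dag, ic, model=model, delta=delta) for d in labels]
    n = len(labels)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = semantic_similarity(profiles[i], profiles[j])
    return SimilarityMatrix(labels=labels, values=values)


def combine_semantic_phenotypic(
    ss: SimilarityMatrix,
    ps: SimilarityMatrix | None,
    omim_mapped: Iterable[str] = (),
) -> SimilarityMatrix:
    """Blend semantic and phenotypic similarity into one disease matrix.

    For pairs where both diseases carry an OMIM number and a phenotypic score
    is available, the combined score is (SS + PS) / 2; every other pair keeps
    its semantic score. The diagonal stays 1.
    """
    mapped = {normalize_id(d) for d in omim_mapped}
    values = ss.values.copy()
    if ps is not None:
        if ps.values.min() < 0 or ps.values.max() > 1:
            raise ValueError("phenotypic similarity values must lie in [0, 1]")
        for i, a in enumerate(ss.labels):
            for j in range(i + 1, len(ss.labels)):
                b = ss.labels[j]
                if a in mapped and b in mapped and a in ps and b in ps:
                    combined = (ss.values[i, j] + ps.loc(a, b)) / 2.0
                    values[i, j] = values[j, i] = combined
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(labels=ss.labels, values=values)
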