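"""Readers and writers for every on-disk artifact the pipeline touches.

All formats are UTF-8, tab-delimited text; lines starting with ``#`` are
comments. Identifiers are normalized on ingest: surrounding whitespace is
trimmed and the string is case-folded, so ``hsa-miR-21`` and ``hsa-mir-21``
refer to the same node in every downstream join.

Formats
-------
associations      two columns: mirna_id <TAB> disease_id
set files (GMT)   name <TAB> description <TAB> member1 <TAB> member2 ...
MeSH tree map     two columns: disease_id <TAB> tree_number (e.g. C04.588.180)
similarity        labelled square matrix, header row + first column of labels
ranked list       columns: rank, candidate_id, score, rank_ratio
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "normalize_id",
    "AssociationTable",
    "GeneSetCollection",
    "MeshDag",
    "SimilarityMatrix",
    "read_associations",
    "read_gmt",
    "read_mesh_tree",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "write_associations",
    "write_gmt",
    "write_mesh_tree",
    "write_ranked_list",
    "read_ranked_list",
    "read_params_file",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


def normalize_id(raw: str) -> str:
    """Trim whitespace and case-fold an identifier."""
    return raw.strip().casefold()


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            yield lineno, stripped


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationTable:
    """The known miRNA-disease link set (gold standard / training edges).

    ``records`` preserves first-seen order and contains no duplicate
    (mirna, disease) pair.
    """

    records: tuple[tuple[str, str], ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        seen: dict[tuple[str, str], None] = {}
        for mirna, disease in pairs:
            m, d = normalize_id(mirna), normalize_id(disease)
            if not m or not d:
                raise ValueError("association identifiers must be non-empty")
            seen.setdefault((m, d))
        return cls(records=tuple(seen))

    @cached_property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.records)

    @cached_property
    def mirnas(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(m for m, _ in self.records))

    @cached_property
    def diseases(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(d for _, d in self.records))

    def associated_mirnas(self, disease: str) -> frozenset[str]:
        return frozenset(m for m, d in self.records if d == disease)

    def associated_diseases(self, mirna: str) -> frozenset[str]:
        return frozenset(d for m, d in self.records if m == mirna)

    def without(self, removed: Iterable[tuple[str, str]]) -> "AssociationTable":
        """A new table with the given pairs deleted (order preserved)."""
        drop = set(removed)
        return AssociationTable(
            records=tuple(r for r in self.records if r not in drop)
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named, deduplicated sets of identifiers (families, clusters, targets)."""

    sets: Mapping[str, tuple[str, ...]]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        out: dict[str, tuple[str, ...]] = {}
        for name, members in mapping.items():
            key = normalize_id(name)
            if key in out:
                raise ValueError(f"duplicate set name: {name!r}")
            out[key] = tuple(dict.fromkeys(normalize_id(m) for m in members))
        return cls(sets=out)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[normalize_id(name)]

    @cached_property
    def _membership(self) -> Mapping[str, tuple[str, ...]]:
        index: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            for member in members:
                index.setdefault(member, []).append(name)
        return {m: tuple(names) for m, names in index.items()}

    def sets_containing(self, member: str) -> tuple[str, ...]:
        """Names of every set the member belongs to (possibly empty)."""
        return self._membership.get(normalize_id(member), ())

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class MeshDag:
    """Disease terms mapped to MeSH-style tree numbers.

    Ancestry is derived purely from tree-number prefixes: the parent of
    ``C04.588.180`` is ``C04.588``. ``dag(d)`` is the set of disease terms
    whose tree numbers are prefixes of any of d's tree numbers, d included.
    """

    terms: Mapping[str, frozenset[str]]

    @cached_property
    def _by_tree_number(self) -> Mapping[str, frozenset[str]]:
        index: dict[str, set[str]] = {}
        for disease, numbers in self.terms.items():
            for tn in numbers:
                index.setdefault(tn, set()).add(disease)
        return {tn: frozenset(ds) for tn, ds in index.items()}

    @staticmethod
    def prefixes(tree_number: str) -> tuple[str, ...]:
        """All dot-segment prefixes of a tree number, longest first."""
        segments = tree_number.split(".")
        return tuple(
            ".".join(segments[:k]) for k in range(len(segments), 0, -1)
        )

    def dag(self, disease: str) -> frozenset[str]:
        """Ancestor disease terms of ``disease`` (self included)."""
        disease = normalize_id(disease)
        if disease not in self.terms:
            raise KeyError(f"unknown disease term: {disease!r}")
        ancestors = {disease}
        for tn in self.terms[disease]:
            for prefix in self.prefixes(tn):
                ancestors.update(self._by_tree_number.get(prefix, ()))
        return frozenset(ancestors)

    def __contains__(self, disease: str) -> bool:
        return normalize_id(disease) in self.terms


class SimilarityMatrix:
    """Symmetric labelled similarity scores in [0, 1] with unit diagonal."""

    def __init__(self, labels: Iterable[str], values: np.ndarray):
        self.labels: tuple[str, ...] = tuple(normalize_id(l) for l in labels)
        values = np.asarray(values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("similarity matrix labels must be unique")
        if values.shape != (n, n):
            raise ValueError(
                f"values shape {values.shape} does not match {n} labels"
            )
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if values.min() < -1e-9 or values.max() > 1 + 1e-9:
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.allclose(np.diag(values), 1.0, atol=1e-9):
            raise ValueError("similarity diagonal must equal 1")
        # exact symmetry / clipping after tolerance checks
        values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(values, 1.0)
        self.values = values
        self._index = {label: i for i, label in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        return float(
            self.values[self._index[normalize_id(a)], self._index[normalize_id(b)]]
        )

    def __contains__(self, label: str) -> bool:
        return normalize_id(label) in self._index

    def index_of(self, label: str) -> int:
        return self._index[normalize_id(label)]

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.values, other.values
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_associations(path: str | Path) -> AssociationTable:
    """Read a two-column miRNA/disease association TSV."""
    path = Path(path)
    pairs: dict[tuple[str, str], None] = {}
    n_read = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(
                f"{path}:{lineno}: expected 'mirna<TAB>disease', got {line!r}"
            )
        n_read += 1
        pairs.setdefault((normalize_id(fields[0]), normalize_id(fields[1])))
    if n_read == 0:
        logger.warning("%s: no association records found", path)
    dropped = n_read - len(pairs)
    logger.info(
        "%s: read %d associations (%d duplicates dropped)", path, len(pairs), dropped
    )
    return AssociationTable(records=tuple(pairs))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT set file (name, description, members...)."""
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs at least name and description"
            )
        name = normalize_id(fields[0])
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = tuple(
            dict.fromkeys(
                normalize_id(f) for f in fields[2:] if f.strip()
            )
        )
        if not members:
            logger.warning("%s:%d: set %r has no members", path, lineno, name)
        sets[name] = members
    return GeneSetCollection(sets=sets)


def read_mesh_tree(path: str | Path) -> MeshDag:
    """Read a two-column disease → tree-number TSV into a :class:`MeshDag`."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(
                f"{path}:{lineno}: expected 'disease<TAB>tree_number'"
            )
        tn = fields[1].strip()
        if any(not segment for segment in tn.split(".")):
            raise ParseError(
                f"{path}:{lineno}: tree number {tn!r} has an empty segment"
            )
        terms.setdefault(normalize_id(fields[0]), set()).add(tn)
    return MeshDag(terms={d: frozenset(tns) for d, tns in terms.items()})


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a labelled square similarity TSV.

    Asymmetric input is symmetrized by averaging, with a warning. Values
    outside [0, 1] beyond 1e-9 raise an error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if frame.shape[0] != frame.shape[1]:
        raise ParseError(f"{path}: similarity body is not square: {frame.shape}")
    labels = [normalize_id(str(l)) for l in frame.index]
    col_labels = [normalize_id(str(l)) for l in frame.columns]
    if labels != col_labels:
        raise ParseError(f"{path}: row and column labels differ")
    values = frame.to_numpy(dtype=float)
    if values.min() < -1e-9 or values.max() > 1 + 1e-9:
        raise ParseError(f"{path}: similarity values outside [0, 1]")
    if not np.allclose(values, values.T, atol=1e-9):
        logger.warning("%s: asymmetric similarity matrix, averaging", path)
        values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(labels=labels, values=values)


def read_ranked_list(path: str | Path) -> pd.DataFrame:
    """Read a ranked-list TSV (rank, candidate_id, score, rank_ratio)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"rank", "candidate_id", "score", "rank_ratio"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: missing ranked-list columns")
    frame["candidate_id"] = frame["candidate_id"].map(lambda s: normalize_id(str(s)))
    return frame.sort_values("rank").reset_index(drop=True)


def read_params_file(path: str | Path) -> dict[str, float]:
    """Read a ``key=value`` parameter file into a flat mapping."""
    out: dict[str, float] = {}
    for lineno, line in _data_lines(Path(path)):
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected 'key=value'")
        key, _, value = line.partition("=")
        try:
            out[key.strip()] = float(value.strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad value {value!r}") from exc
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_associations(table: AssociationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for mirna, disease in table.records:
            handle.write(f"{mirna}\t{disease}\n")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in collection.sets.items():
            handle.write("\t".join([name, "na", *members]) + "\n")


def write_mesh_tree(dag: MeshDag, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for disease in sorted(dag.terms):
            for tn in sorted(dag.terms[disease]):
                handle.write(f"{disease}\t{tn}\n")


def write_similarity_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    frame.to_csv(path, sep="\t", float_format="%.12g")


def write_ranked_list(ranked, path: str | Path) -> None:
    """Write a :class:`~mirflow.maxflow.RankedList` as a ranked-list TSV."""
    if not len(ranked):
        raise ValueError("refusing to write an empty ranked list")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("rank\tcandidate_id\tscore\trank_ratio\n")
        for entry in ranked.entries:
            handle.write(
                f"{entry.rank}\t{entry.candidate_id}\t{entry.score:.12g}"
                f"\t{entry.rank_ratio:.12g}\n"
            )
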