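"""Readers and writers for every on-disk representation used by the pipeline.

All other modules operate on the in-memory domain types defined here
(:class:`EntityRegistry`, :class:`AssociationMatrix`, :class:`SequenceSet`,
:class:`DiseaseDag`); nothing downstream touches files directly.

Canonical interchange formats are plain text: TSV/CSV pair lists for
associations, labeled TSV square tables for similarity matrices, FASTA for
miRNA sequences, a TAB-separated parent/child edge list for the disease
ontology, and a long-format TSV for prediction scores.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("midgae")

MIRNA = "miRNA"
DISEASE = "disease"

_HEADER_WORDS = {"mirna", "mirna name", "disease", "disease name", "name", "id", "mir"}

_RNA_ALPHABET = frozenset("ACGUN")


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


def normalize_name(name: str, kind: str = MIRNA) -> str:
    """Canonicalize an entity identifier before matching across sources.

    Lowercases, trims whitespace, collapses internal runs of whitespace, and —
    for miRNAs — repairs the common ``has-mir`` misspelling of the ``hsa-mir``
    species prefix.  Lowercasing also unifies the ``hsa-mir``/``hsa-miR``
    capitalization variants seen in curated tables.
    """
    s = re.sub(r"\s+", " ", name.strip()).lower()
    if kind == MIRNA:
        s = re.sub(r"^has-mir", "hsa-mir", s)
    return s


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityRegistry:
    """An ordered, deduplicated set of entity names with 0-based positions.

    ``index`` is a bijection name -> 0..n-1.  Ordering is the insertion order
    of first appearance as produced by the builder that created the registry
    (file readers preserve file order; set-based builders sort).
    """

    kind: str
    names: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_names(cls, kind: str, names: Iterable[str], *, sort: bool = False) -> "EntityRegistry":
        seen: dict[str, int] = {}
        for raw in names:
            key = normalize_name(raw, kind)
            if not key:
                raise FormatError(f"empty {kind} name")
            if key not in seen:
                seen[key] = len(seen)
        ordered = sorted(seen) if sort else list(seen)
        return cls(kind=kind, names=tuple(ordered), index={n: i for i, n in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name, self.kind) in self.index

    def position(self, name: str) -> int:
        key = normalize_name(name, self.kind)
        if key not in self.index:
            raise KeyError(f"unknown {self.kind} name: {name!r}")
        return self.index[key]


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary nm x nd matrix of verified miRNA-disease links.

    Rows follow the miRNA registry, columns the disease registry; an entry of
    1 marks an experimentally verified association, 0 an unverified pair.
    """

    values: np.ndarray
    mirnas: EntityRegistry
    diseases: EntityRegistry

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape != (len(self.mirnas), len(self.diseases)):
            raise ValueError(
                f"association matrix shape {v.shape} does not match registries "
                f"({len(self.mirnas)} x {len(self.diseases)})"
            )
        if not np.isin(v, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        object.__setattr__(self, "values", v.astype(np.float64))

    @property
    def nm(self) -> int:
        return len(self.mirnas)

    @property
    def nd(self) -> int:
        return len(self.diseases)

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        return AssociationMatrix(values=values, mirnas=self.mirnas, diseases=self.diseases)


@dataclass(frozen=True)
class SequenceSet:
    """RNA sequences keyed by miRNA name, aligned to a registry.

    Sequences are stored in a single canonical alphabet {A,C,G,U,N}; DNA input
    (T) is converted on load.
    """

    registry: EntityRegistry
    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name in self.registry.names:
            seq = self.sequences.get(name)
            if not seq:
                raise ValueError(f"missing or empty sequence for miRNA {name!r}")
            bad = set(seq) - _RNA_ALPHABET
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in sequence of {name!r}")

    def __getitem__(self, name: str) -> str:
        return self.sequences[normalize_name(name, MIRNA)]

    def reconcile(self, registry: EntityRegistry, *, strict: bool = True) -> "SequenceSet":
        """Re-key this set onto an association-derived registry.

        Every registry name must have a sequence (always an error otherwise).
        Extra sequences are an error in strict mode and are dropped with a log
        message in permissive mode.
        """
        missing = [n for n in registry.names if n not in self.sequences]
        if missing:
            raise FormatError(f"no sequence for registry miRNAs: {missing[:10]}")
        extra = sorted(set(self.sequences) - set(registry.names))
        if extra:
            if strict:
                raise FormatError(f"sequences not in registry: {extra[:10]}")
            logger.info("dropping %d sequences absent from registry", len(extra))
        return SequenceSet(
            registry=registry, sequences={n: self.sequences[n] for n in registry.names}
        )


@dataclass(frozen=True)
class DiseaseDag:
    """A MeSH-style directed acyclic graph of disease terms.

    Edges point parent -> child.  For a disease D, ``ancestor_closure(D)``
    is the node set T(D) containing D itself plus all its ancestors, and
    ``subgraph_edges(D)`` is the edge set E(D) of direct parent-child links
    within T(D).
    """

    registry: EntityRegistry
    edges: frozenset[tuple[str, str]]
    _graph: nx.DiGraph = field(repr=False, compare=False)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "DiseaseDag":
        norm_edges = []
        names: list[str] = []
        for parent, child in edges:
            p, c = normalize_name(parent, DISEASE), normalize_name(child, DISEASE)
            if not p or not c:
                raise FormatError(f"empty node name in edge ({parent!r}, {child!r})")
            norm_edges.append((p, c))
            names.extend((p, c))
        g = nx.DiGraph(norm_edges)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise FormatError(f"disease hierarchy contains a cycle: {path}")
        registry = EntityRegistry.from_names(DISEASE, names)
        return cls(registry=registry, edges=frozenset(norm_edges), _graph=g)

    def ancestor_closure(self, disease: str) -> frozenset[str]:
        key = normalize_name(disease, DISEASE)
        if key not in self._graph:
            raise KeyError(f"unknown disease term: {disease!r}")
        return frozenset(nx.ancestors(self._graph, key)) | {key}

    def subgraph_edges(self, disease: str) -> frozenset[tuple[str, str]]:
        closure = self.ancestor_closure(disease)
        return frozenset((p, c) for p, c in self.edges if p in closure and c in closure)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(self._graph.successors(normalize_name(node, DISEASE)))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _delimiter(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _looks_like_header(fields: Sequence[str]) -> bool:
    return any(normalize_name(f, DISEASE) in _HEADER_WORDS for f in fields[:2])


def read_associations(path: str | Path, dialect: str | None = None) -> AssociationMatrix:
    """Read a two-column miRNA/disease pair list into a binary matrix.

    Duplicate pairs collapse to a single 1, so the matrix sum equals the
    number of unique pairs.  Registries keep first-appearance order.  An
    optional header row is detected by its column labels.  XLSX input is
    accepted as a reader dialect (first sheet, same two-column contract).
    """
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        frame = pd.read_excel(path, header=None, dtype=str)
        rows = [tuple("" if pd.isna(x) else str(x) for x in r) for r in frame.itertuples(index=False)]
    else:
        sep = _delimiter(path, dialect)
        with open(path, newline="", encoding="utf-8") as fh:
            rows = [tuple(r) for r in csv.reader(fh, delimiter=sep)]
    rows = [(i + 1, r) for i, r in enumerate(rows) if any(f.strip() for f in r)]
    if not rows:
        raise FormatError(f"{path}: empty association file")
    if _looks_like_header(rows[0][1]):
        rows = rows[1:]
        if not rows:
            raise FormatError(f"{path}: header but no data rows")

    pairs: list[tuple[str, str]] = []
    for lineno, fields in rows:
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise FormatError(f"{path}:{lineno}: expected miRNA and disease fields, got {fields!r}")
        pairs.append((fields[0], fields[1]))

    mirnas = EntityRegistry.from_names(MIRNA, (m for m, _ in pairs))
    diseases = EntityRegistry.from_names(DISEASE, (d for _, d in pairs))
    values = np.zeros((len(mirnas), len(diseases)))
    for m, d in pairs:
        values[mirnas.position(m), diseases.position(d)] = 1.0
    return AssociationMatrix(values=values, mirnas=mirnas, diseases=diseases)


def read_similarity_matrix(
    path: str | Path,
    registry: EntityRegistry,
    *,
    dialect: str | None = None,
    tolerance: float = 1e-6,
    source: str = "precomputed",
):
    """Read a labeled square similarity table aligned to ``registry``.

    Row and column labels must cover the registry exactly (offenders are
    listed on mismatch); rows/columns are reordered to registry order.
    Entries must be finite and in [0, 1]; the matrix must be symmetric to
    within ``tolerance`` and is exactly symmetrized on return.
    """
    from .similarity import SimilarityMatrix  # local import avoids a cycle

    path = Path(path)
    sep = _delimiter(path, dialect)
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = [normalize_name(str(n), registry.kind) for n in frame.index]
    frame.columns = [normalize_name(str(n), registry.kind) for n in frame.columns]
    if list(frame.index) != list(frame.columns):
        raise FormatError(f"{path}: row labels differ from column labels")
    want, have = set(registry.names), set(frame.index)
    if want != have:
        missing, extra = sorted(want - have), sorted(have - want)
        raise FormatError(
            f"{path}: labels do not match registry (missing {missing[:10]}, extra {extra[:10]})"
        )
    frame = frame.loc[list(registry.names), list(registry.names)]
    values = frame.to_numpy(dtype=np.float64)
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite entries")
    if values.min() < 0.0 or values.max() > 1.0:
        raise FormatError(
            f"{path}: entries outside [0, 1] (min {values.min():g}, max {values.max():g})"
        )
    asym = np.abs(values - values.T).max()
    if asym > tolerance:
        raise FormatError(f"{path}: asymmetric beyond tolerance (max |S - S^T| = {asym:g})")
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values=values, registry=registry, source=source)


def read_fasta(path: str | Path) -> SequenceSet:
    """Read multi-line FASTA into a :class:`SequenceSet` (T converted to U)."""
    from Bio import SeqIO

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}: sequence data before the first FASTA header")
                break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    sequences: dict[str, str] = {}
    order: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        name = normalize_name(record.id, MIRNA)
        seq = str(record.seq).upper().replace("T", "U")
        if not seq:
            raise FormatError(f"{path}: record {record.id!r} has no sequence")
        if name not in sequences:
            order.append(name)
        sequences[name] = seq
    registry = EntityRegistry.from_names(MIRNA, order)
    return SequenceSet(registry=registry, sequences=sequences)


def read_dag(path: str | Path) -> DiseaseDag:
    """Read a parent<TAB>child edge list into a :class:`DiseaseDag`."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError(f"{path}:{lineno}: expected parent<TAB>child, got {line!r}")
            edges.append((fields[0], fields[1]))
    if not edges:
        raise FormatError(f"{path}: no edges")
    return DiseaseDag.from_edges(edges)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_scores(
    scores: np.ndarray,
    mirnas: EntityRegistry,
    diseases: EntityRegistry,
    path: str | Path,
    *,
    digits: int = 12,
) -> None:
    """Write an nm x nd score matrix as long-format TSV, best score first.

    Columns are miRNA, disease, score; rows sort by descending score with
    registry order breaking ties, so re-reading reproduces the matrix.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (len(mirnas), len(diseases)):
        raise ValueError(f"score matrix shape {scores.shape} does not match registries")
    flat = [
        (mirnas.names[i], diseases.names[j], scores[i, j])
        for i in range(len(mirnas))
        for j in range(len(diseases))
    ]
    flat.sort(key=lambda t: (-t[2], mirnas.position(t[0]), diseases.position(t[1])))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\tdisease\tscore\n")
        for m, d, s in flat:
            fh.write(f"{m}\t{d}\t{s:.{digits}g}\n")


def read_scores(
    path: str | Path, mirnas: EntityRegistry, diseases: EntityRegistry
) -> np.ndarray:
    """Inverse of :func:`write_scores` for round-trip checks and reuse."""
    frame = pd.read_csv(path, sep="\t")
    out = np.full((len(mirnas), len(diseases)), np.nan)
    for m, d, s in frame.itertuples(index=False):
        out[mirnas.position(str(m)), diseases.position(str(d))] = float(s)
    if np.isnan(out).any():
        raise FormatError(f"{path}: score table does not cover every pair")
    return out


def write_matrix(
    values: np.ndarray,
    registry_rows: EntityRegistry,
    registry_cols: EntityRegistry,
    path: str | Path,
    *,
    digits: int = 6,
) -> None:
    """Write a labeled numeric table as TSV with ``digits`` significant digits."""
    frame = pd.DataFrame(values, index=registry_rows.names, columns=registry_cols.names)
    frame.to_csv(path, sep="\t", float_format=f"%.{digits}g")
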