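"""Similarity kernels for miRNAs and diseases, and their integration.

Four base matrices feed the heterogeneous network:

* ``SM1`` — miRNA sequence similarity from global (Needleman-Wunsch)
  alignment scores, normalized to [0, 1];
* ``SD1`` — disease semantic similarity from the MeSH-style DAG via the
  Wang recursion (each ancestor's contribution decays multiplicatively per
  edge of distance);
* ``SM2`` / ``SD2`` — Gaussian interaction profile (GIP) kernels computed
  from the binary association matrix A, with the bandwidth normalized by the
  mean squared profile norm;

and the integrated ``SM`` / ``SD`` average the primary and GIP similarity
wherever the primary similarity is nonzero, falling back to the GIP kernel
where it is structurally zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from Bio import Align

from .io_formats import AssociationMatrix, DiseaseDag, EntityRegistry, SequenceSet

MIRNA_AXIS = "miRNA"
DISEASE_AXIS = "disease"


@dataclass(frozen=True)
class SimilarityMatrix:
    """A square, symmetric, [0,1]-valued similarity matrix over a registry."""

    values: np.ndarray
    registry: EntityRegistry
    source: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.registry)
        if v.shape != (n, n):
            raise ValueError(f"similarity shape {v.shape} does not match registry size {n}")
        if not np.isfinite(v).all():
            raise ValueError("similarity entries must be finite")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError(f"similarity entries outside [0,1]: min {v.min()}, max {v.max()}")
        if np.abs(v - v.T).max() > 1e-9:
            raise ValueError("similarity matrix is not symmetric")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    @property
    def n(self) -> int:
        return len(self.registry)


@dataclass(frozen=True)
class GipConfig:
    """Bandwidth control for the GIP kernel; the derived bandwidth is
    ``raw_bandwidth`` divided by the mean squared profile norm."""

    raw_bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.raw_bandwidth <= 0:
            raise ValueError("raw_bandwidth must be positive")


@dataclass(frozen=True)
class AlignmentScoring:
    """Needleman-Wunsch scoring: linear gap penalty, per-position match and
    mismatch scores.  Defaults (1/0/0) make the score a longest-common-
    subsequence count, so dividing by the longer length lands in [0,1]."""

    match: float = 1.0
    mismatch: float = 0.0
    gap: float = 0.0

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap > 0:
            raise ValueError("gap penalty must be <= 0")


@dataclass(frozen=True)
class WangConfig:
    """Decay factor for semantic contributions along DAG edges, in (0,1)."""

    decay: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must lie strictly between 0 and 1")


# ---------------------------------------------------------------------------
# GIP kernel
# ---------------------------------------------------------------------------


def _profiles(a: AssociationMatrix, axis: str) -> np.ndarray:
    if axis == MIRNA_AXIS:
        return a.values
    if axis == DISEASE_AXIS:
        return a.values.T
    raise ValueError(f"axis must be {MIRNA_AXIS!r} or {DISEASE_AXIS!r}, got {axis!r}")


def gip_bandwidth(a: AssociationMatrix, axis: str, cfg: GipConfig = GipConfig()) -> float:
    """Derived GIP bandwidth: raw bandwidth over the mean squared norm of the
    interaction profiles along ``axis``."""
    p = _profiles(a, axis)
    mean_sq = float((p * p).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ZeroDivisionError(
            "GIP bandwidth undefined: association matrix has no verified links "
            "(mean squared profile norm is zero)"
        )
    return cfg.raw_bandwidth / mean_sq


def gip_kernel(a: AssociationMatrix, axis: str, cfg: GipConfig = GipConfig()) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over association profiles.

    S(i,j) = exp(-rho * ||P(i) - P(j)||^2) with rho from :func:`gip_bandwidth`;
    symmetric with unit diagonal.
    """
    p = _profiles(a, axis)
    rho = gip_bandwidth(a, axis, cfg)
    sq_norms = (p * p).sum(axis=1)
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (p @ p.T)
    np.clip(d2, 0.0, None, out=d2)
    s = np.exp(-rho * d2)
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    registry = a.mirnas if axis == MIRNA_AXIS else a.diseases
    return SimilarityMatrix(values=s, registry=registry, source="gip")


# ---------------------------------------------------------------------------
# miRNA sequence similarity
# ---------------------------------------------------------------------------


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    return aligner

def sequence_similarity(
    seqs: SequenceSet, scoring: AlignmentScoring = AlignmentScoring()
) -> SimilarityMatrix:
    """Pairwise global-alignment similarity, normalized to [0, 1].

    SM1(i,j) = max(NW(i,j), 0) / (match * max(|s_i|, |s_j|)); the diagonal is
    exactly 1 because a sequence aligned to itself scores match per position.
    """
    names = seqs.registry.names
    n = len(names)
    if n == 0:
        raise ValueError("empty sequence set")
    for name in names:
        if not seqs.sequences[name]:
            raise ValueError(f"empty sequence for {name!r}")
    aligner = _aligner(scoring)
    values = np.eye(n)
    for i in range(n):
        si = seqs.sequences[names[i]]
        for j in range(i + 1, n):
            sj = seqs.sequences[names[j]]
            score = aligner.score(si, sj)
            sim = max(score, 0.0) / (scoring.match * max(len(si), len(sj)))
            values[i, j] = values[j, i] = min(sim, 1.0)
    return SimilarityMatrix(values=values, registry=seqs.registry, source="sequence")


# ---------------------------------------------------------------------------
# Disease semantic similarity (Wang DAG recursion)
# ---------------------------------------------------------------------------


def _contributions(dag: DiseaseDag, disease: str, decay: float) -> dict[str, float]:
    """Semantic contribution of every term in T(D) to disease D.

    The disease itself contributes 1; an ancestor contributes ``decay`` times
    the largest contribution among its children inside DAG(D).
    """
    closure = dag.ancestor_closure(disease)
    memo: dict[str, float] = {}

    def value(term: str) -> float:
        if term in memo:
            return memo[term]
        if term == disease:
            memo[term] = 1.0
        else:
            kids = [c for c in dag.children(term) if c in closure]
            memo[term] = decay * max(value(c) for c in kids)
        return memo[term]

    return {t: value(t) for t in closure}


def semantic_similarity(
    dag: DiseaseDag,
    cfg: WangConfig = WangConfig(),
    registry: EntityRegistry | None = None,
) -> SimilarityMatrix:
    """Wang-style DAG semantic similarity between diseases.

    SD1(di,dj) sums the contributions of shared ancestors from both diseases'
    DAGs and divides by the two total semantic values, giving a symmetric
    matrix with unit diagonal.  ``registry`` restricts the output to a subset
    of DAG terms (e.g. the diseases present in the association matrix).
    """
    registry = registry or dag.registry
    contribs = []
    totals = []
    for name in registry.names:
        c = _contributions(dag, name, cfg.decay)
        contribs.append(c)
        totals.append(sum(c.values()))
    n = len(registry)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = contribs[i].keys() & contribs[j].keys()
            if shared:
                num = sum(contribs[i][t] + contribs[j][t] for t in shared)
                values[i, j] = values[j, i] = num / (totals[i] + totals[j])
    return SimilarityMatrix(values=values, registry=registry, source="semantic")


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def integrate(primary: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Combine a primary (sequence/semantic) matrix with the GIP kernel.

    Where the primary similarity is nonzero the two are averaged; where it is
    exactly zero (a structural zero, not a rounding artifact) the GIP value is
    used alone.
    """
    if primary.registry.names != gip.registry.names:
        raise ValueError("cannot integrate similarity matrices over different registries")
    p, g = primary.values, gip.values
    out = np.where(p != 0.0, (p + g) / 2.0, g)
    return SimilarityMatrix(values=out, registry=primary.registry, source="integrated")


def integrated_similarities(
    a: AssociationMatrix,
    sm1: SimilarityMatrix,
    sd1: SimilarityMatrix,
    gip_cfg: GipConfig = GipConfig(),
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Convenience: compute SM2/SD2 from ``a`` and integrate with SM1/SD1."""
    sm2 = gip_kernel(a, MIRNA_AXIS, gip_cfg)
    sd2 = gip_kernel(a, DISEASE_AXIS, gip_cfg)
    return integrate(sm1, sm2), integrate(sd1, sd2)
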