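"""Heterogeneous network assembly and threshold-binarized sub-networks.

The integrated similarity matrices SM and SD are symmetrically normalized
(D^{-1/2} S D^{-1/2}) and combined with the association matrix A into the
block feature matrix X = [[M, A], [A^T, D]] over nm miRNA nodes followed by
nd disease nodes.  Two sub-networks drive the two autoencoder instances: the
miRNA-based graph keeps similarity edges S(i,j) >= tm between miRNAs plus all
association edges; the disease-based graph keeps S(i,j) >= td between
diseases plus the association edges.  Both share X as node features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AssociationMatrix, EntityRegistry
from .similarity import SimilarityMatrix

MIRNA_BASED = "miRNA-based"
DISEASE_BASED = "disease-based"


def normalize_similarity(s: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} S D^{-1/2}.

    Requires strictly positive row sums (guaranteed when the diagonal is 1);
    the result is symmetric with spectral radius at most 1.
    """
    values = s.values if isinstance(s, SimilarityMatrix) else np.asarray(s, dtype=np.float64)
    row_sums = values.sum(axis=1)
    if (row_sums <= 0).any():
        bad = np.flatnonzero(row_sums <= 0)
        raise ValueError(f"cannot normalize: zero row sums at indices {bad[:10].tolist()}")
    inv_sqrt = 1.0 / np.sqrt(row_sums)
    return inv_sqrt[:, None] * values * inv_sqrt[None, :]


@dataclass(frozen=True)
class HeterogeneousFeatures:
    """The (nm+nd) x (nm+nd) block feature matrix X with its registries.

    Row i < nm is the feature vector of miRNA i: its normalized similarities
    to every miRNA followed by its association profile.  Rows nm..nm+nd-1
    hold the disease feature vectors symmetrically.
    """

    X: np.ndarray
    mirnas: EntityRegistry
    diseases: EntityRegistry

    @property
    def nm(self) -> int:
        return len(self.mirnas)

    @property
    def nd(self) -> int:
        return len(self.diseases)

    @property
    def n(self) -> int:
        return self.nm + self.nd


def build_features(
    sm: SimilarityMatrix, sd: SimilarityMatrix, a: AssociationMatrix
) -> HeterogeneousFeatures:
    """Assemble X = [[M, A], [A^T, D]] from normalized SM, SD and A."""
    nm, nd = a.nm, a.nd
    if sm.values.shape != (nm, nm) or sd.values.shape != (nd, nd):
        raise ValueError(
            f"shape mismatch: SM {sm.values.shape}, SD {sd.values.shape}, A {a.values.shape}"
        )
    m = normalize_similarity(sm)
    d = normalize_similarity(sd)
    x = np.block([[m, a.values], [a.values.T, d]])
    return HeterogeneousFeatures(X=x, mirnas=a.mirnas, diseases=a.diseases)


@dataclass(frozen=True)
class SubNetwork:
    """A binary (nm+nd)-node graph: one thresholded similarity block plus the
    bipartite association edges, sharing the heterogeneous features X.

    The diagonal is zero; self-loops are added only inside the encoder's
    propagation matrix (adj + I).  The opposite-type similarity block is all
    zeros: the miRNA-based graph carries no disease-disease edges and vice
    versa.
    """

    kind: str
    adj: np.ndarray
    threshold: float
    features: HeterogeneousFeatures

    @property
    def nm(self) -> int:
        return self.features.nm

    @property
    def nd(self) -> int:
        return self.features.nd


def binarize_similarity(values: np.ndarray, threshold: float) -> np.ndarray:
    """1 where similarity >= threshold off the diagonal, else 0 (inclusive
    comparison; the unit self-similarity never creates a self-edge)."""
    out = (values >= threshold).astype(np.float64)
    np.fill_diagonal(out, 0.0)
    return out


def build_subnetwork(
    kind: str,
    similarity: SimilarityMatrix,
    a: AssociationMatrix,
    threshold: float,
    features: HeterogeneousFeatures | None = None,
) -> SubNetwork:
    """Build the miRNA-based or disease-based sub-network at ``threshold``.

    ``similarity`` is the integrated SM (miRNA-based) or SD (disease-based);
    thresholding applies to these raw [0,1] similarities, not the normalized
    blocks of X.  Because X needs both SM and SD, callers normally pass the
    shared ``features`` explicitly (see :func:`build_both_subnetworks`); when
    omitted, identity features are used as a placeholder.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    nm, nd = a.nm, a.nd
    n = nm + nd
    adj = np.zeros((n, n))
    adj[:nm, nm:] = a.values
    adj[nm:, :nm] = a.values.T
    if kind == MIRNA_BASED:
        if similarity.values.shape != (nm, nm):
            raise ValueError("miRNA-based sub-network needs an nm x nm similarity matrix")
        adj[:nm, :nm] = binarize_similarity(similarity.values, threshold)
    elif kind == DISEASE_BASED:
        if similarity.values.shape != (nd, nd):
            raise ValueError("disease-based sub-network needs an nd x nd similarity matrix")
        adj[nm:, nm:] = binarize_similarity(similarity.values, threshold)
    else:
        raise ValueError(f"kind must be {MIRNA_BASED!r} or {DISEASE_BASED!r}, got {kind!r}")
    if features is None:
        features = HeterogeneousFeatures(X=np.eye(n), mirnas=a.mirnas, diseases=a.diseases)
    elif features.X.shape != (n, n):
        raise ValueError("feature matrix shape does not match the association registries")
    return SubNetwork(kind=kind, adj=adj, threshold=threshold, features=features)


def build_both_subnetworks(
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
    a: AssociationMatrix,
    tm: float = 0.9,
    td: float = 0.9,
) -> tuple[SubNetwork, SubNetwork]:
    """Standard pipeline step: shared features X, then both sub-networks."""
    feats = build_features(sm, sd, a)
    sub_m = build_subnetwork(MIRNA_BASED, sm, a, tm, feats)
    sub_d = build_subnetwork(DISEASE_BASED, sd, a, td, feats)
    return sub_m, sub_d
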