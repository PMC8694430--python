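"""Cross-validation protocols, ensemble scoring, AUC, and ranked export.

The full method trains one autoencoder per sub-network and averages the two
miRNA-disease score blocks, A* = (m* + d*) / 2.  Evaluation follows the
standard bipartite link-prediction protocol: verified pairs are split into
folds, each fold's positives are masked to zero in the training matrix, all
derived quantities (GIP kernels, integrated similarities, features, both
sub-network adjacencies) are recomputed from the masked matrix so no held-out
link leaks into training, and the held-out positives are pooled against all
unverified pairs into a single ROC.

A ``naive_gip`` flag reproduces the variant that computes GIP kernels from
the full association matrix even during cross-validation; it is provided for
comparison and is not the default.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .gcae import GcaeConfig, LossConfig, ScoreMatrix, train
from .io_formats import AssociationMatrix, EntityRegistry, normalize_name
from .network_builder import build_both_subnetworks
from .similarity import GipConfig, SimilarityMatrix, integrated_similarities

logger = logging.getLogger("midgae")

FIVEFOLD = "fivefold"
LOOCV = "loocv"

# Published results for this architecture on the full HMDD v3.2 benchmark
# (853 miRNAs, 591 diseases, 12446 verified links, with the curated sequence
# and semantic similarity matrices): repeated five-fold AUC about 0.9415 and
# global leave-one-out AUC about 0.9505.  Soft reference points for
# paper-scale runs with those inputs; nothing in this package asserts them.
REFERENCE_FULL_SCALE_AUCS = {FIVEFOLD: 0.9415, LOOCV: 0.9505}

# A scorer maps a (masked) training association matrix to an nm x nd score
# array; injecting one bypasses model training (metric plumbing, baselines).
Scorer = Callable[[AssociationMatrix], np.ndarray]


@dataclass(frozen=True)
class FoldPlan:
    """A seeded, reproducible partition of the verified-positive pairs.

    ``partitions`` holds ``repeats`` independent partitions; each partition
    is a list of (k, 2) integer arrays of held-out (miRNA, disease) indices.
    Five-fold partitions have fold sizes differing by at most one;
    leave-one-out has one positive per fold.
    """

    protocol: str
    partitions: tuple[tuple[np.ndarray, ...], ...]
    seed: int
    repeats: int

    @property
    def folds(self) -> tuple[np.ndarray, ...]:
        return tuple(f for part in self.partitions for f in part)


def make_folds(
    a: AssociationMatrix,
    protocol: str = FIVEFOLD,
    seed: int = 0,
    repeats: int = 1,
    *,
    n_folds: int = 5,
    max_folds: int | None = None,
) -> FoldPlan:
    """Partition the positive pairs for cross-validation.

    ``max_folds`` (leave-one-out only) subsamples that many positives, each
    held out alone — a desk-scale surrogate for the full protocol, which
    trains one model pair per verified association.
    """
    positives = np.argwhere(a.values == 1.0)
    if protocol == FIVEFOLD:
        if len(positives) < n_folds:
            raise ValueError(f"need at least {n_folds} positives, have {len(positives)}")
    elif protocol == LOOCV:
        if len(positives) < 1:
            raise ValueError("leave-one-out needs at least one positive")
    else:
        raise ValueError(f"protocol must be {FIVEFOLD!r} or {LOOCV!r}, got {protocol!r}")

    partitions = []
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        order = rng.permutation(len(positives))
        if protocol == FIVEFOLD:
            parts = tuple(positives[idx] for idx in np.array_split(order, n_folds))
        else:
            if max_folds is not None and max_folds < len(order):
                order = order[:max_folds]
            parts = tuple(positives[i][None, :] for i in order)
        partitions.append(parts)
    return FoldPlan(protocol=protocol, partitions=tuple(partitions), seed=seed, repeats=repeats)


@dataclass
class EvalResult:
    """Pooled and per-fold cross-validation outcomes."""

    auc: float
    auc_mirna: float
    auc_disease: float
    per_fold_aucs: list[float]
    fpr: np.ndarray
    tpr: np.ndarray
    predictions: ScoreMatrix
    leaked_edges: int  # structural audit: held-out links found in any training graph
    per_repeat_aucs: list[float] = field(default_factory=list)


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (trapezoidal; ties by midrank, equivalent to
    the Mann-Whitney U statistic)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores)))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fpr, tpr, _ = roc_curve(np.asarray(labels), np.asarray(scores))
    return fpr, tpr


def ensemble(m_star: ScoreMatrix | np.ndarray, d_star: ScoreMatrix | np.ndarray) -> ScoreMatrix:
    """A* = (m* + d*) / 2 on the miRNA-disease probability blocks."""
    m = m_star.cross if isinstance(m_star, ScoreMatrix) else np.asarray(m_star)
    d = d_star.cross if isinstance(d_star, ScoreMatrix) else np.asarray(d_star)
    if m.shape != d.shape:
        raise ValueError(f"cannot ensemble score blocks of shapes {m.shape} and {d.shape}")
    return ScoreMatrix.from_cross((m + d) / 2.0)


def _model_scores(
    a_train: AssociationMatrix,
    a_gip: AssociationMatrix,
    sm1: SimilarityMatrix,
    sd1: SimilarityMatrix,
    cfg: GcaeConfig,
    gip_cfg: GipConfig,
    tm: float,
    td: float,
    seed: int,
    loss_cfg: LossConfig,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Train both sub-network models on a (possibly masked) matrix.

    ``a_gip`` is the matrix the GIP kernels see: equal to ``a_train`` in
    leakage-free mode, the full matrix in naive mode.  Returns the two cross
    score blocks and the structural leak count of the training adjacencies.
    """
    sm, sd = integrated_similarities(a_gip, sm1, sd1, gip_cfg)
    sub_m, sub_d = build_both_subnetworks(sm, sd, a_train, tm, td)
    nm = a_train.nm
    held_out = (a_train.values == 0.0)
    leaks = int((sub_m.adj[:nm, nm:] * held_out).sum() + (sub_d.adj[:nm, nm:] * held_out).sum())
    res_m = train(sub_m, GcaeConfig(**{**vars(cfg), "seed": seed}), loss_cfg)
    res_d = train(sub_d, GcaeConfig(**{**vars(cfg), "seed": seed + 1}), loss_cfg)
    return res_m.scores.cross, res_d.scores.cross, leaks


def run_cv(
    a: AssociationMatrix,
    sm1: SimilarityMatrix,
    sd1: SimilarityMatrix,
    cfg: GcaeConfig,
    plan: FoldPlan,
    *,
    gip_cfg: GipConfig = GipConfig(),
    tm: float = 0.9,
    td: float = 0.9,
    loss_cfg: LossConfig = LossConfig(),
    naive_gip: bool = False,
    scorer: Scorer | None = None,
) -> EvalResult:
    """Cross-validate the two-model ensemble under ``plan``.

    Per fold: held-out positives are zeroed in the training matrix; every
    derived quantity is recomputed from the masked matrix (unless
    ``naive_gip``); both models are trained with fold-specific seeds; scores
    for the held-out positives and all unverified pairs are pooled into one
    ROC per repeat.  The reported AUCs average over repeats.  ``scorer``
    replaces the model entirely (metric checks, baselines).
    """
    nm, nd = a.nm, a.nd
    repeat_aucs, repeat_aucs_m, repeat_aucs_d = [], [], []
    per_fold_aucs: list[float] = []
    total_leaks = 0
    pooled_scores_first: np.ndarray | None = None
    pooled_labels_first: np.ndarray | None = None
    pred_sum = np.zeros((nm, nd))
    n_models = 0

    for partition in plan.partitions:
        rep_scores, rep_scores_m, rep_scores_d, rep_labels = [], [], [], []
        for fold_idx, held in enumerate(partition):
            masked = a.values.copy()
            masked[held[:, 0], held[:, 1]] = 0.0
            a_train = a.with_values(masked)
            if scorer is not None:
                cross_m = cross_d = np.asarray(scorer(a_train), dtype=np.float64)
                leaks = 0
            else:
                fold_seed = (plan.seed * 100003 + fold_idx * 2) % (2**31 - 1)
                a_gip = a if naive_gip else a_train
                cross_m, cross_d, leaks = _model_scores(
                    a_train, a_gip, sm1, sd1, cfg, gip_cfg, tm, td, fold_seed, loss_cfg
                )
            total_leaks += leaks
            cross = ensemble(cross_m, cross_d).cross
            pred_sum += cross
            n_models += 1

            # Pool: held-out positives against every pair outside the
            # training positive set.
            eval_mask = a_train.values == 0.0
            labels = np.zeros((nm, nd))
            labels[held[:, 0], held[:, 1]] = 1.0
            rep_scores.append(cross[eval_mask])
            rep_scores_m.append(cross_m[eval_mask])
            rep_scores_d.append(cross_d[eval_mask])
            rep_labels.append(labels[eval_mask])
            per_fold_aucs.append(compute_auc(cross[eval_mask], labels[eval_mask]))

        sc = np.concatenate(rep_scores)
        lb = np.concatenate(rep_labels)
        repeat_aucs.append(compute_auc(sc, lb))
        repeat_aucs_m.append(compute_auc(np.concatenate(rep_scores_m), lb))
        repeat_aucs_d.append(compute_auc(np.concatenate(rep_scores_d), lb))
        if pooled_scores_first is None:
            pooled_scores_first, pooled_labels_first = sc, lb

    fpr, tpr = roc_points(pooled_scores_first, pooled_labels_first)
    return EvalResult(
        auc=float(np.mean(repeat_aucs)),
        auc_mirna=float(np.mean(repeat_aucs_m)),
        auc_disease=float(np.mean(repeat_aucs_d)),
        per_fold_aucs=per_fold_aucs,
        fpr=fpr,
        tpr=tpr,
        predictions=ScoreMatrix.from_cross(pred_sum / max(n_models, 1)),
        leaked_edges=total_leaks,
        per_repeat_aucs=[float(x) for x in repeat_aucs],
    )


def fit_and_score(
    a: AssociationMatrix,
    sm1: SimilarityMatrix,
    sd1: SimilarityMatrix,
    cfg: GcaeConfig,
    *,
    gip_cfg: GipConfig = GipConfig(),
    tm: float = 0.9,
    td: float = 0.9,
    loss_cfg: LossConfig = LossConfig(),
) -> ScoreMatrix:
    """Train on the full association matrix and return the ensemble scores
    (the prediction mode used for ranked candidate export)."""
    cross_m, cross_d, _ = _model_scores(
        a, a, sm1, sd1, cfg, gip_cfg, tm, td, cfg.seed, loss_cfg
    )
    return ensemble(cross_m, cross_d)


def rank_predictions(
    a_star: ScoreMatrix | np.ndarray,
    a_train: AssociationMatrix,
    query: str,
    *,
    kind: str = "disease",
    k: int = 50,
) -> list[tuple[str, float]]:
    """Top-k novel candidates for one disease (or one miRNA).

    Candidates are pairs unverified in ``a_train``; they sort by descending
    score with registry order breaking ties.  An unknown query raises with
    close-match suggestions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = a_star.cross if isinstance(a_star, ScoreMatrix) else np.asarray(a_star)
    if kind == "disease":
        registry, other = a_train.diseases, a_train.mirnas
    elif kind == "miRNA":
        registry, other = a_train.mirnas, a_train.diseases
    else:
        raise ValueError(f"kind must be 'disease' or 'miRNA', got {kind!r}")
    key = normalize_name(query, registry.kind)
    if key not in registry.index:
        hints = difflib.get_close_matches(key, registry.names, n=3)
        raise KeyError(f"unknown {kind} {query!r}" + (f"; did you mean {hints}?" if hints else ""))
    q = registry.index[key]
    if kind == "disease":
        col_scores, known = scores[:, q], a_train.values[:, q]
    else:
        col_scores, known = scores[q, :], a_train.values[q, :]
    candidates = [(i, col_scores[i]) for i in range(len(other)) if known[i] == 0.0]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return [(other.names[i], float(s)) for i, s in candidates[:k]]


def grid_experiment(
    a: AssociationMatrix,
    sm1: SimilarityMatrix,
    sd1: SimilarityMatrix,
    cfg: GcaeConfig,
    tm_list: Sequence[float],
    td_list: Sequence[float],
    *,
    seed: int = 0,
    repeats: int = 1,
    **cv_kwargs,
) -> pd.DataFrame:
    """Five-fold ensemble AUC for every (tm, td) threshold combination,
    with a fixed fold plan across cells."""
    plan = make_folds(a, FIVEFOLD, seed=seed, repeats=repeats)
    table = pd.DataFrame(index=list(tm_list), columns=list(td_list), dtype=float)
    for tm in tm_list:
        for td in td_list:
            result = run_cv(a, sm1, sd1, cfg, plan, tm=tm, td=td, **cv_kwargs)
            table.loc[tm, td] = result.auc
            logger.info("grid tm=%.2f td=%.2f auc=%.4f", tm, td, result.auc)
    return table
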