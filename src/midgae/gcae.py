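"""The graph-convolutional autoencoder (GCAE) over one sub-network.

Architecture
------------
Encoder: three graph-convolution layers.  Each layer computes

    H(l) = ReLU( D^{-1/2} (adj + I) D^{-1/2} H(l-1) W(l) )

with H(0) = X (the heterogeneous feature matrix) and D the degree matrix of
the self-loop-augmented adjacency.  A layer-attention step fuses the
per-layer embeddings into h = sum_l a_l H(l), with the weights a_l either
learned (softmax-parameterized, so nonnegative and summing to one at every
step) or fixed; lower layers typically receive more weight, counteracting
over-smoothing.  H(0) is excluded from the fusion since its width differs
from the embedding width.

Decoder: inner product — the reconstructed link logits are h h^T and
probabilities their elementwise sigmoid, scoring every node pair at once.

Loss: positive-weighted binary cross-entropy between the sub-network
adjacency and the reconstruction, with the positive weight defaulting to the
#negatives / #positives ratio of the target to counter class imbalance.
Training is full-batch Adam, entirely deterministic given the seed.

The forward and backward passes are written directly in numpy; gradients are
derived by hand for this fixed architecture, which keeps the model free of
framework dependencies and makes bitwise reproducibility straightforward.
Per-layer random streams (weight init and dropout) are spawned from the seed
by position, so a single-layer model draws exactly the same layer-1 numbers
as the first layer of a deeper model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import json
import numpy as np

from .network_builder import SubNetwork

ATTENTION_LEARNED = "learned"
ATTENTION_FIXED = "fixed"


@dataclass(frozen=True)
class GcaeConfig:
    """Hyperparameters of one GCAE instance.

    Defaults follow the reference setting: 3 layers of width 64, learning
    rate 1e-4 (Adam), 400 epochs, dropout 0.3, and fixed attention weights
    50/35/15 when ``attention_mode='fixed'``.
    """

    n_layers: int = 3
    embed_dim: int = 64
    dropout: float = 0.3
    learning_rate: float = 1e-4
    epochs: int = 400
    attention_mode: str = ATTENTION_LEARNED
    fixed_weights: tuple[float, ...] = (0.50, 0.35, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.attention_mode not in (ATTENTION_LEARNED, ATTENTION_FIXED):
            raise ValueError(f"unknown attention mode {self.attention_mode!r}")
        fw = tuple(float(w) for w in self.fixed_weights)
        if len(fw) != self.n_layers:
            raise ValueError("fixed_weights length must equal n_layers")
        if abs(sum(fw) - 1.0) > 1e-9:
            raise ValueError("fixed_weights must sum to 1")
        object.__setattr__(self, "fixed_weights", fw)


@dataclass(frozen=True)
class LossConfig:
    """Positive-class weight for the reconstruction cross-entropy."""

    pos_weight: float | None = None  # None: #zeros / #ones of the target

    def resolve(self, target: np.ndarray) -> float:
        if self.pos_weight is not None:
            if self.pos_weight <= 0:
                raise ValueError("pos_weight must be positive")
            return self.pos_weight
        ones = float(target.sum())
        if ones == 0:
            raise ValueError("target adjacency has no positive entries; pos_weight undefined")
        return (target.size - ones) / ones


@dataclass
class EncoderState:
    """Weights, attention parameters and derived embeddings of one encoder."""

    W: list[np.ndarray]
    attn_logits: np.ndarray | None  # None in fixed-attention mode
    a: np.ndarray  # attention weights, nonneg, sum 1
    H: list[np.ndarray] = field(default_factory=list)  # H(0)..H(L), eval mode
    h: np.ndarray | None = None  # fused embedding


@dataclass(frozen=True)
class ScoreMatrix:
    """Reconstruction scores: full-logit view plus the miRNA-disease block."""

    logits: np.ndarray | None
    cross_probs: np.ndarray
    nm: int
    nd: int

    @classmethod
    def from_logits(cls, logits: np.ndarray, nm: int, nd: int) -> "ScoreMatrix":
        probs = _sigmoid(logits)
        return cls(logits=logits, cross_probs=probs[:nm, nm:], nm=nm, nd=nd)

    @classmethod
    def from_cross(cls, probs: np.ndarray) -> "ScoreMatrix":
        probs = np.asarray(probs, dtype=np.float64)
        return cls(logits=None, cross_probs=probs, nm=probs.shape[0], nd=probs.shape[1])

    @property
    def probabilities(self) -> np.ndarray:
        if self.logits is None:
            raise ValueError("full probability view unavailable: cross-block-only scores")
        return _sigmoid(self.logits)

    @property
    def cross(self) -> np.ndarray:
        return self.cross_probs


@dataclass
class TrainResult:
    """Everything :func:`train` produces: final state, reconstruction, and
    per-epoch loss and attention-weight traces."""

    state: EncoderState
    scores: ScoreMatrix
    loss_trace: np.ndarray
    attention_trace: np.ndarray  # epochs x n_layers


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def propagation_matrix(adj: np.ndarray) -> np.ndarray:
    """Renormalized propagation operator D^{-1/2} (adj + I) D^{-1/2}.

    Self-loops guarantee every row sum is >= 1, so no isolated-node division
    can occur (asserted).
    """
    a_hat = adj + np.eye(adj.shape[0])
    deg = a_hat.sum(axis=1)
    assert (deg >= 1.0).all(), "self-loops guarantee degree >= 1"
    inv_sqrt = 1.0 / np.sqrt(deg)
    return inv_sqrt[:, None] * a_hat * inv_sqrt[None, :]


def gcn_layer(
    h_prev: np.ndarray,
    sub: SubNetwork,
    w: np.ndarray,
    *,
    training: bool = False,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One graph-convolution layer: ReLU of the renormalized propagation.

    Dropout (inverted scaling) is applied to the output only during training.
    """
    p = propagation_matrix(sub.adj)
    out = np.maximum(p @ h_prev @ w, 0.0)
    if training and dropout > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        mask = (rng.random(out.shape) >= dropout) / (1.0 - dropout)
        out = out * mask
    return out


def _streams(cfg: GcaeConfig) -> tuple[list[np.random.Generator], list[np.random.Generator]]:
    """Positionally spawned per-layer random streams (init, dropout).

    Child sequences depend only on their spawn index, so layer l of any model
    with >= l layers draws identical numbers.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(1 + 2 * cfg.n_layers)
    init = [np.random.default_rng(children[2 * l + 1]) for l in range(cfg.n_layers)]
    drop = [np.random.default_rng(children[2 * l + 2]) for l in range(cfg.n_layers)]
    return init, drop


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_state(sub: SubNetwork, cfg: GcaeConfig) -> EncoderState:
    """Glorot-uniform weights and uniform (zero-logit) attention, seeded."""
    n = sub.adj.shape[0]
    init_rngs, _ = _streams(cfg)
    dims = [n] + [cfg.embed_dim] * cfg.n_layers
    weights = [_glorot(init_rngs[l], dims[l], dims[l + 1]) for l in range(cfg.n_layers)]
    if cfg.attention_mode == ATTENTION_LEARNED:
        logits = np.zeros(cfg.n_layers)
        a = _attention_weights(logits, cfg)
    else:
        logits = None
        a = np.asarray(cfg.fixed_weights)
    return EncoderState(W=weights, attn_logits=logits, a=a)


def _attention_weights(logits: np.ndarray | None, cfg: GcaeConfig) -> np.ndarray:
    if cfg.attention_mode == ATTENTION_FIXED:
        return np.asarray(cfg.fixed_weights)
    e = logits - logits.max()
    ex = np.exp(e)
    return ex / ex.sum()


def _fuse(a: np.ndarray, hs: list[np.ndarray]) -> np.ndarray:
    """h = sum_l a_l H(l); exact-zero weights are skipped so degenerate
    attention (e.g. [1,0,0]) reproduces the shallower model bitwise."""
    h = np.zeros_like(hs[0])
    for w, mat in zip(a, hs):
        if w != 0.0:
            h = h + w * mat
    return h


def encode(sub: SubNetwork, cfg: GcaeConfig, state: EncoderState | None = None) -> EncoderState:
    """Evaluation-mode forward pass; returns the state with H(0..L) and the
    fused embedding h filled in.  Initializes fresh weights when ``state``
    is None."""
    if state is None:
        state = init_state(sub, cfg)
    p = propagation_matrix(sub.adj)
    hs = [sub.features.X]
    for w in state.W:
        hs.append(np.maximum(p @ hs[-1] @ w, 0.0))
    a = _attention_weights(state.attn_logits, cfg)
    state.a = a
    state.H = hs
    state.h = _fuse(a, hs[1:])
    return state


def decode(h: np.ndarray, nm: int | None = None, nd: int | None = None) -> ScoreMatrix:
    """Inner-product decoder: logits h h^T, probabilities via sigmoid."""
    logits = h @ h.T
    n = logits.shape[0]
    if nm is None:
        nm, nd = n, 0
    return ScoreMatrix.from_logits(logits, nm, nd if nd is not None else n - nm)


def weighted_bce(
    scores: ScoreMatrix | np.ndarray,
    target: np.ndarray,
    loss_cfg: LossConfig = LossConfig(),
) -> float:
    """Mean positive-weighted binary cross-entropy, computed stably from
    logits: mean of  w*t*softplus(-s) + (1-t)*softplus(s)."""
    logits = scores.logits if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    if logits is None:
        raise ValueError("loss needs the logit view of the scores")
    target = np.asarray(target, dtype=np.float64)
    if logits.shape != target.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs target {target.shape}")
    omega = loss_cfg.resolve(target)
    loss = omega * target * _softplus(-logits) + (1.0 - target) * _softplus(logits)
    return float(loss.mean())


def train(
    sub: SubNetwork, cfg: GcaeConfig, loss_cfg: LossConfig = LossConfig()
) -> TrainResult:
    """Full-batch Adam training of one GCAE instance on its sub-network.

    The target of the reconstruction loss is the sub-network adjacency
    itself (the whole (nm+nd)^2 matrix); only the miRNA-disease cross block
    of the final reconstruction is used for prediction.  Deterministic given
    ``cfg.seed``.  Raises on a non-finite loss with the epoch and learning
    rate in the message.
    """
    state = init_state(sub, cfg)
    _, drop_rngs = _streams(cfg)
    x = sub.features.X
    target = sub.adj
    n = x.shape[0]
    p = propagation_matrix(sub.adj)
    omega = loss_cfg.resolve(target)
    learned = cfg.attention_mode == ATTENTION_LEARNED

    params: list[np.ndarray] = list(state.W) + ([state.attn_logits] if learned else [])
    adam_m = [np.zeros_like(q) for q in params]
    adam_v = [np.zeros_like(q) for q in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    losses = np.zeros(cfg.epochs)
    attn_trace = np.zeros((cfg.epochs, cfg.n_layers))
    inv_n2 = 1.0 / target.size

    for epoch in range(cfg.epochs):
        # --- forward (training mode) ---
        hs = [x]
        zs, masks, phs = [], [], []
        for l, w in enumerate(state.W):
            ph = p @ hs[-1]
            z = ph @ w
            r = np.maximum(z, 0.0)
            if cfg.dropout > 0.0:
                mask = (drop_rngs[l].random(r.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
                hcur = r * mask
            else:
                mask = None
                hcur = r
            phs.append(ph)
            zs.append(z)
            masks.append(mask)
            hs.append(hcur)
        a = _attention_weights(state.attn_logits, cfg)
        h = _fuse(a, hs[1:])
        logits = h @ h.T
        loss = float(
            (omega * target * _softplus(-logits) + (1.0 - target) * _softplus(logits)).mean()
        )
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch} (learning rate {cfg.learning_rate:g})"
            )
        losses[epoch] = loss
        attn_trace[epoch] = a

        # --- backward ---
        sig = _sigmoid(logits)
        g = ((1.0 - target) * sig - omega * target * (1.0 - sig)) * inv_n2
        dh = (g + g.T) @ h
        d_hs = [w * dh if w != 0.0 else np.zeros_like(dh) for w in a]
        da = np.array([float((dh * hl).sum()) for hl in hs[1:]])
        grads_w: list[np.ndarray] = [None] * cfg.n_layers  # type: ignore[list-item]
        for l in range(cfg.n_layers - 1, -1, -1):
            dr = d_hs[l] * masks[l] if masks[l] is not None else d_hs[l]
            dz = dr * (zs[l] > 0.0)
            grads_w[l] = phs[l].T @ dz
            if l > 0:
                d_hs[l - 1] = d_hs[l - 1] + p @ (dz @ state.W[l].T)
        grads: list[np.ndarray] = list(grads_w)
        if learned:
            grads.append(a * (da - float(da @ a)))  # softmax backward

        # --- Adam update ---
        t = epoch + 1
        for q, gq, m, v in zip(params, grads, adam_m, adam_v):
            m *= beta1
            m += (1.0 - beta1) * gq
            v *= beta2
            v += (1.0 - beta2) * gq * gq
            m_hat = m / (1.0 - beta1**t)
            v_hat = v / (1.0 - beta2**t)
            q -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

    state = encode(sub, cfg, state)
    scores = decode(state.h, sub.nm, sub.nd)
    return TrainResult(state=state, scores=scores, loss_trace=losses, attention_trace=attn_trace)


# ---------------------------------------------------------------------------
# Checkpointing (plain-text arrays + JSON config snapshot)
# ---------------------------------------------------------------------------


def save_checkpoint(result: TrainResult, cfg: GcaeConfig, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for l, w in enumerate(result.state.W):
        np.savetxt(directory / f"W{l + 1}.tsv", w, delimiter="\t")
    np.savetxt(directory / "attention.tsv", result.state.a, delimiter="\t")
    if result.state.attn_logits is not None:
        np.savetxt(directory / "attention_logits.tsv", result.state.attn_logits, delimiter="\t")
    np.savetxt(directory / "loss_trace.tsv", result.loss_trace, delimiter="\t")
    with open(directory / "config.json", "w", encoding="utf-8") as fh:
        json.dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()},
            fh,
            indent=2,
        )


def load_checkpoint(directory: str | Path) -> tuple[EncoderState, GcaeConfig]:
    directory = Path(directory)
    with open(directory / "config.json", encoding="utf-8") as fh:
        raw = json.load(fh)
    raw["fixed_weights"] = tuple(raw["fixed_weights"])
    cfg = GcaeConfig(**raw)
    weights = [
        np.loadtxt(directory / f"W{l + 1}.tsv", delimiter="\t", ndmin=2)
        for l in range(cfg.n_layers)
    ]
    a = np.loadtxt(directory / "attention.tsv", delimiter="\t", ndmin=1)
    logits_path = directory / "attention_logits.tsv"
    logits = np.loadtxt(logits_path, delimiter="\t", ndmin=1) if logits_path.exists() else None
    return EncoderState(W=weights, attn_logits=logits, a=a), cfg
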