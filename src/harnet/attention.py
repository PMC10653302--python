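"""Sparse self-attention (slide + random) and the Transformer encoder.

Full self-attention scores every query–key pair, which is quadratic in
the sequence length. The sparse pattern used here keeps only

* a *sliding band*: each position attends to its 2w+1 nearest
  neighbours, preserving local sensitivity to short signal fluctuations;
* *random attention*: each position additionally attends to a few
  uniformly sampled positions, providing cheap global context.

The union of the two (plus the always-allowed diagonal) forms the mask;
the fraction of the t×t score matrix it removes is the mask fraction
(default: 70% of pairs removed, so ~30% density retained). Attention is
computed as masked dense math — disallowed logits are pushed to −1e9
before the softmax — and a FLOPs accountant reports the arithmetic a
sparse kernel would actually perform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, relu, softmax
from .layers import LayerNorm, Linear, Module

__all__ = [
    "AttentionMask",
    "EncoderConfig",
    "ProjectionSet",
    "slide_mask",
    "random_mask",
    "har_mask",
    "masked_multihead_attention",
    "MultiHeadSelfAttention",
    "EncoderLayer",
    "Encoder",
    "attention_flops",
    "save_mask_txt",
]

logger = logging.getLogger(__name__)

NEG_INF = -1e9


@dataclass
class AttentionMask:
    """Boolean t×t matrix: ``allowed[q, k]`` means query q may attend to key k.

    Every diagonal entry is forced true so no row is empty.
    """

    allowed: np.ndarray

    def __post_init__(self):
        self.allowed = np.asarray(self.allowed, dtype=bool)
        t = self.allowed.shape[0]
        if self.allowed.shape != (t, t):
            raise ValueError("mask must be square")
        if not self.allowed.diagonal().all():
            raise ValueError("every position must attend to itself")

    @property
    def t(self) -> int:
        return self.allowed.shape[0]

    @property
    def density(self) -> float:
        """Fraction of the t² score entries retained."""
        return float(self.allowed.mean())

    def union(self, other: "AttentionMask") -> "AttentionMask":
        return AttentionMask(self.allowed | other.allowed)

    def bias(self) -> np.ndarray:
        """Additive logit bias: 0 where allowed, −1e9 where masked."""
        return np.where(self.allowed, 0.0, NEG_INF)


@dataclass
class EncoderConfig:
    """Hyperparameters of the sparse Transformer encoder."""

    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    ffn_dim: int | None = None      # defaults to 4 * d_model
    dropout: float = 0.1
    slide_radius: int = 5
    mask_fraction: float = 0.7      # fraction of t² pairs removed
    mask_is_keep_fraction: bool = False   # alternative reading: fraction kept
    use_sparse_mask: bool = True    # ablation switch: full attention when False

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError(f"d_model ({self.d_model}) must be divisible by "
                             f"n_heads ({self.n_heads})")
        if not 0.0 <= self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must be in [0, 1]")
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.d_model

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    @property
    def keep_fraction(self) -> float:
        return self.mask_fraction if self.mask_is_keep_fraction \
            else 1.0 - self.mask_fraction


@dataclass
class ProjectionSet:
    """Per-head query/key/value projections plus the output projection.

    ``w_q``, ``w_k``, ``w_v``: [n_heads, d, d']; ``w_out``: [d, d].
    """

    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    w_out: np.ndarray

    def __post_init__(self):
        nh, d, dp = self.w_q.shape
        for name in ("w_k", "w_v"):
            if getattr(self, name).shape != (nh, d, dp):
                raise ValueError(f"{name} shape inconsistent with w_q")
        if self.w_out.shape != (d, d):
            raise ValueError("output projection must be d × d")
        if nh * dp != d:
            raise ValueError("head_dim × n_heads must equal d_model")


# -- mask construction --------------------------------------------------------


def slide_mask(t: int, radius: int) -> AttentionMask:
    """Band mask: position q attends to keys within ``radius`` steps."""
    if t < 1 or radius < 0:
        raise ValueError("t must be >= 1 and radius >= 0")
    idx = np.arange(t)
    return AttentionMask(np.abs(idx[:, None] - idx[None, :]) <= radius)


def random_mask(t: int, r_per_row: int, seed) -> AttentionMask:
    """Each row attends to ``r_per_row`` uniformly sampled keys plus itself."""
    if not 0 <= r_per_row <= t:
        raise ValueError("r_per_row must be in [0, t]")
    rng = np.random.default_rng(seed)
    allowed = np.zeros((t, t), dtype=bool)
    for q in range(t):
        allowed[q, rng.choice(t, size=r_per_row, replace=False)] = True
    np.fill_diagonal(allowed, True)
    return AttentionMask(allowed)


def har_mask(t: int, config: EncoderConfig, seed) -> AttentionMask:
    """Union of the sliding band and per-row random attention.

    The number of random keys per row is chosen so the total retained
    density approximates ``keep_fraction``:
    ``r_per_row = max(0, round(keep_fraction · t) − (2w + 1))``. If the
    band alone exceeds the budget, the band is kept and a warning logged.
    """
    w = config.slide_radius
    band_width = 2 * w + 1
    budget = int(round(config.keep_fraction * t))
    r_per_row = budget - band_width
    if r_per_row < 0:
        logger.warning("sliding band (width %d) alone exceeds the attention "
                       "budget (%d keys/row); keeping the band, no random keys",
                       band_width, budget)
        r_per_row = 0
    r_per_row = min(r_per_row, t)
    return slide_mask(t, w).union(random_mask(t, r_per_row, seed))


def full_mask(t: int) -> AttentionMask:
    return AttentionMask(np.ones((t, t), dtype=bool))


def save_mask_txt(path, mask: AttentionMask):
    """Export a mask as a plain 0/1 text matrix."""
    np.savetxt(path, mask.allowed.astype(int), fmt="%d")


# -- attention math -----------------------------------------------------------


def masked_multihead_attention(seq: np.ndarray, proj: ProjectionSet,
                               mask: AttentionMask) -> np.ndarray:
    """Masked multi-head self-attention on a single [t, d] sequence.

    Per head h: Q = X·W_qʰ, K = X·W_kʰ, V = X·W_vʰ (each t × d');
    scores = Q·Kᵀ / √d′ with masked pairs pushed to −∞ before the
    row softmax; the heads' outputs concatenate and pass through the
    output projection. Rows of the result are convex combinations of V
    rows restricted to each query's allowed keys.
    """
    X = np.asarray(seq, dtype=float)
    t, d = X.shape
    nh, _, dp = proj.w_q.shape
    if mask.t != t:
        raise ValueError("mask size does not match sequence length")
    bias = mask.bias()
    heads = []
    for h in range(nh):
        Q = X @ proj.w_q[h]
        K = X @ proj.w_k[h]
        V = X @ proj.w_v[h]
        scores = Q @ K.T / np.sqrt(dp) + bias
        scores -= scores.max(axis=-1, keepdims=True)
        weights = np.exp(scores)
        weights /= weights.sum(axis=-1, keepdims=True)
        heads.append(weights @ V)
    out = np.concatenate(heads, axis=-1) @ proj.w_out
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("numeric overflow in attention")
    return out


class MultiHeadSelfAttention(Module):
    """Trainable masked multi-head self-attention: [B, t, d] → [B, t, d]."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        d = config.d_model
        self.n_heads = config.n_heads
        self.head_dim = config.head_dim
        self.q_proj = Linear(d, d, rng)
        self.k_proj = Linear(d, d, rng)
        self.v_proj = Linear(d, d, rng)
        self.out_proj = Linear(d, d, rng)

    def forward(self, x: Tensor, mask: AttentionMask) -> Tensor:
        B, t, d = x.shape
        nh, dp = self.n_heads, self.head_dim

        def split_heads(z: Tensor) -> Tensor:
            return z.reshape(B, t, nh, dp).transpose(0, 2, 1, 3)   # [B, nh, t, d']

        Q = split_heads(self.q_proj(x))
        K = split_heads(self.k_proj(x))
        V = split_heads(self.v_proj(x))
        scores = (Q @ K.transpose(0, 1, 3, 2)) * float(1.0 / np.sqrt(dp))
        scores = scores + mask.bias().astype(x.data.dtype)[None, None]
        weights = softmax(scores)
        out = (weights @ V).transpose(0, 2, 1, 3).reshape(B, t, d)
        out = self.out_proj(out)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("numeric overflow in attention")
        return out

    def projection_set(self) -> ProjectionSet:
        """Export the learned projections in per-head layout (biases folded out)."""
        nh, dp, d = self.n_heads, self.head_dim, self.n_heads * self.head_dim
        reshape = lambda w: w.reshape(d, nh, dp).transpose(1, 0, 2)
        return ProjectionSet(reshape(self.q_proj.weight.data),
                             reshape(self.k_proj.weight.data),
                             reshape(self.v_proj.weight.data),
                             self.out_proj.weight.data)


class EncoderLayer(Module):
    """Post-norm Transformer layer: masked attention and a position-wise
    feed-forward block, each wrapped in residual + layer normalisation."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        d = config.d_model
        self.attn = MultiHeadSelfAttention(config, rng)
        self.norm1 = LayerNorm(d)
        self.norm2 = LayerNorm(d)
        self.ffn1 = Linear(d, config.ffn_dim, rng)
        self.ffn2 = Linear(config.ffn_dim, d, rng)
        self.dropout = config.dropout

    def _maybe_dropout(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        if not self.training or self.dropout <= 0 or rng is None:
            return x
        keep = 1.0 - self.dropout
        mask = ((rng.random(x.shape) < keep) / keep).astype(x.data.dtype)
        return x * Tensor(mask)

    def forward(self, x: Tensor, mask: AttentionMask,
                rng: np.random.Generator | None = None) -> Tensor:
        x = self.norm1(x + self._maybe_dropout(self.attn(x, mask), rng))
        x = self.norm2(x + self._maybe_dropout(self.ffn2(relu(self.ffn1(x))), rng))
        return x


class Encoder(Module):
    """Stack of encoder layers sharing one attention mask."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.layers = [EncoderLayer(config, rng) for _ in range(config.n_layers)]

    def forward(self, x: Tensor, mask: AttentionMask,
                rng: np.random.Generator | None = None) -> Tensor:
        for layer in self.layers:
            x = layer(x, mask, rng)
        return x


# -- FLOPs accounting ---------------------------------------------------------


def attention_flops(t: int, d: int, config: EncoderConfig,
                    mask: AttentionMask | None = None, seed=0) -> dict:
    """Score/weighting FLOPs of dense vs. sparse attention for one layer.

    Dense attention computes Q·Kᵀ and A·V over all t² query–key pairs
    (2 multiply-accumulates per pair per head dimension); a sparse
    kernel performs the same arithmetic only on unmasked pairs, so the
    sparse/dense ratio equals the mask density exactly.
    """
    if mask is None:
        mask = har_mask(t, config, seed) if config.use_sparse_mask else full_mask(t)
    pairs = int(mask.allowed.sum())
    per_pair = 2 * 2 * config.head_dim * config.n_heads   # QKᵀ + AV, mul+add
    dense = per_pair * t * t
    sparse = per_pair * pairs
    return {"dense": dense, "sparse": sparse, "ratio": pairs / float(t * t)}
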