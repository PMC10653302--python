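"""Squeeze-and-excitation channel attention fused with a 1-D CNN embedding.

The channels of a wearable-sensor window (accelerometer and gyroscope
axes) are not equally informative for every activity. The SE block
learns a per-channel gate: each channel is *squeezed* to a scalar by
global average pooling, the vector of scalars passes through a two-layer
bottleneck (rectifier, then sigmoid), and the resulting gates in (0, 1)
rescale the raw channels. The gated window is then embedded by a stack
of same-length 1-D convolutions into a ``t × d`` feature sequence
(t equal to the window length) for the Transformer encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .autodiff import Tensor, relu, sigmoid
from .layers import Conv1dSame, Linear, Module

__all__ = [
    "SEConfig",
    "ChannelWeights",
    "EmbeddingSequence",
    "SEBlock",
    "ConvEmbedding",
    "SEChannelEmbedding",
    "squeeze",
    "excite",
    "reweight",
    "conv_embed",
]


@dataclass
class SEConfig:
    """Architecture of the SE + convolutional embedding stage."""

    reduction_ratio: int = 2
    conv_kernel_sizes: tuple[int, ...] = (7, 5)   # 140/100 ms receptive fields at 50 Hz
    conv_out_channels: tuple[int, ...] = (32, 64)
    use_se: bool = True     # ablation switch: plain 1-D CNN when False

    def __post_init__(self):
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        if len(self.conv_kernel_sizes) != len(self.conv_out_channels):
            raise ValueError("one kernel size per conv layer required")
        if any(k % 2 == 0 for k in self.conv_kernel_sizes):
            raise ValueError("same-length padding impossible: kernel sizes must be odd")

    @property
    def d_model(self) -> int:
        return self.conv_out_channels[-1]


@dataclass
class ChannelWeights:
    """Learned per-channel gates, each strictly inside (0, 1)."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class EmbeddingSequence:
    """A length-t, dimension-d feature sequence."""

    features: np.ndarray    # [t, d]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("embedding contains non-finite values")


# -- functional forms of the SE operations (numpy in, numpy out) --------------


def squeeze(values: np.ndarray) -> np.ndarray:
    """Global average pooling: each channel compressed to its mean.

    Accepts [C, L] or a batch [B, C, L]; pools over the last axis.
    """
    return np.asarray(values, dtype=float).mean(axis=-1)


def excite(squeezed: np.ndarray, fc1_weight: np.ndarray, fc1_bias: np.ndarray,
           fc2_weight: np.ndarray, fc2_bias: np.ndarray) -> ChannelWeights:
    """Two-layer excitation: ``sigmoid(W2 · relu(W1 · s + b1) + b2)``.

    Weight matrices map ``[in, out]`` so a squeezed vector of length C
    requires ``fc1_weight`` of shape [C, hidden] and ``fc2_weight`` of
    shape [hidden, C].
    """
    s = np.asarray(squeezed, dtype=float)
    if s.shape[-1] != fc1_weight.shape[0] or fc2_weight.shape[1] != fc1_weight.shape[0]:
        raise ValueError("excitation dimension error: FC shapes do not match channels")
    hidden = np.maximum(s @ fc1_weight + fc1_bias, 0.0)
    return ChannelWeights(expit(hidden @ fc2_weight + fc2_bias))


def reweight(values: np.ndarray, gates: ChannelWeights | np.ndarray) -> np.ndarray:
    """Scale each channel by its gate, elementwise over time."""
    g = gates.weights if isinstance(gates, ChannelWeights) else np.asarray(gates)
    values = np.asarray(values, dtype=float)
    if g.shape[-1] != values.shape[-2]:
        raise ValueError("excitation dimension error: one gate per channel required")
    return values * g[..., :, None]


# -- trainable modules --------------------------------------------------------


class SEBlock(Module):
    """Squeeze → excite → reweight, as a trainable module.

    Input [B, C, L] → gated output [B, C, L] plus the gates [B, C].
    """

    def __init__(self, n_channels: int, reduction_ratio: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, int(np.ceil(n_channels / reduction_ratio)))
        self.fc1 = Linear(n_channels, hidden, rng)
        self.fc2 = Linear(hidden, n_channels, rng)

    def gates(self, x: Tensor) -> Tensor:
        squeezed = x.mean(axis=-1)                     # [B, C]
        return sigmoid(self.fc2(relu(self.fc1(squeezed))))

    def forward(self, x: Tensor) -> Tensor:
        g = self.gates(x)
        B, C = g.shape
        return x * g.reshape(B, C, 1)


class ConvEmbedding(Module):
    """Stack of same-length 1-D convolutions: [B, C, L] → [B, t=L, d].

    A rectifier follows every layer except the last, which stays linear
    (``activations=False`` disables all nonlinearities, making the map
    linear for fixed parameters).
    """

    def __init__(self, n_channels: int, config: SEConfig, rng: np.random.Generator,
                 activations: bool = True):
        super().__init__()
        self.activations = activations
        self.convs = []
        c_in = n_channels
        for c_out, k in zip(config.conv_out_channels, config.conv_kernel_sizes):
            self.convs.append(Conv1dSame(c_in, c_out, k, rng))
            c_in = c_out

    def forward(self, x: Tensor) -> Tensor:
        for i, conv in enumerate(self.convs):
            x = conv(x)
            if self.activations and i < len(self.convs) - 1:
                x = relu(x)
        return x.transpose(0, 2, 1)    # [B, L, d]


class SEChannelEmbedding(Module):
    """The full input stage: SE gating on raw channels, then conv embedding.

    Channel reweighting happens on the raw window *before* any
    convolution, so the gates act on physical sensor channels.
    """

    def __init__(self, n_channels: int, config: SEConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.se = SEBlock(n_channels, config.reduction_ratio, rng) if config.use_se else None
        self.conv = ConvEmbedding(n_channels, config, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.se is not None:
            x = self.se(x)
        return self.conv(x)


def conv_embed(values: np.ndarray, embedding: ConvEmbedding) -> EmbeddingSequence:
    """Run the convolutional embedding on a single [C, L] window."""
    x = Tensor(np.asarray(values, dtype=float)[None])
    out = embedding(x)
    return EmbeddingSequence(out.data[0])
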