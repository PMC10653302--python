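"""Sinusoidal positional encoding.

Activity signals are periodic, so the same sample value means different
things at different positions in a window. Positions are encoded with
the fixed interleaved sine/cosine table

    PE[pos, 2i]   = sin(pos / 10000^(2i / d_model))
    PE[pos, 2i+1] = cos(pos / 10000^(2i / d_model))

whose wavelengths form a geometric progression from 2π to 10000·2π.
The table is precomputed once, so adding it to a sequence is a lookup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingSequence

__all__ = ["PositionalEncoding", "build_pe", "add_pe"]


@dataclass
class PositionalEncoding:
    table: np.ndarray   # [max_positions, d_model], entries in [-1, 1]

    @property
    def max_positions(self) -> int:
        return self.table.shape[0]

    @property
    def d_model(self) -> int:
        return self.table.shape[1]


def build_pe(max_positions: int, d_model: int) -> PositionalEncoding:
    """Precompute the sinusoidal table for positions 0..max_positions−1."""
    if d_model % 2 != 0:
        raise ValueError("d_model must be even")
    if max_positions < 1:
        raise ValueError("max_positions must be at least 1")
    pos = np.arange(max_positions, dtype=float)[:, None]
    i = np.arange(d_model // 2, dtype=float)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / d_model)
    table = np.empty((max_positions, d_model))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles)
    return PositionalEncoding(table)


def add_pe(seq: EmbeddingSequence, pe: PositionalEncoding) -> EmbeddingSequence:
    """Add the first t rows of the table to a length-t sequence."""
    t, d = seq.features.shape
    if t > pe.max_positions:
        raise ValueError("sequence exceeds encoding table")
    if d != pe.d_model:
        raise ValueError(f"dimension mismatch: sequence d={d}, table d={pe.d_model}")
    return EmbeddingSequence(seq.features + pe.table[:t])
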