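"""Parameterized building blocks: dense layers, embeddings and LSTM cells."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Dense", "Embedding", "LSTMCell", "glorot", "uniform_init"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def uniform_init(rng: np.random.Generator, shape, scale: float = 0.05) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


class Dense:
    """y = x @ W + b."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int) -> None:
        self.W = ad.parameter(glorot(rng, n_in, n_out))
        self.b = ad.parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.W) + self.b

    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class Embedding:
    """Lookup table; rows listed in ``frozen_rows`` are re-zeroed after every
    optimizer step (used for the all-zero padding vector)."""

    def __init__(
        self,
        rng: np.random.Generator,
        n_rows: int,
        dim: int,
        scale: float = 0.05,
        frozen_rows: tuple[int, ...] = (),
    ) -> None:
        self.table = ad.parameter(uniform_init(rng, (n_rows, dim), scale))
        self.frozen_rows = frozen_rows
        for r in frozen_rows:
            self.table.data[r] = 0.0

    def __call__(self, idx: np.ndarray) -> Tensor:
        return ad.take(self.table, idx)

    def enforce_frozen(self) -> None:
        for r in self.frozen_rows:
            self.table.data[r] = 0.0

    def params(self) -> list[Tensor]:
        return [self.table]


class LSTMCell:
    """Standard LSTM cell (input/forget/output gates + candidate), gate order
    [i, f, g, o]; the forget-gate bias is initialized to 1."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int) -> None:
        self.n_hidden = n_hidden
        self.W = ad.parameter(glorot(rng, n_in, 4 * n_hidden))
        self.U = ad.parameter(glorot(rng, n_hidden, 4 * n_hidden))
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0
        self.b = ad.parameter(b)

    def step(
        self, x: Tensor, h: Tensor, c: Tensor, mask: np.ndarray | None = None
    ) -> tuple[Tensor, Tensor]:
        """One timestep over a batch. ``mask`` (B, 1) freezes state for padded
        positions (mask 0 keeps the previous h and c)."""
        H = self.n_hidden
        z = (x @ self.W) + (h @ self.U) + self.b
        i = ad.sigmoid(ad.slice_cols(z, 0, H))
        f = ad.sigmoid(ad.slice_cols(z, H, 2 * H))
        g = ad.tanh(ad.slice_cols(z, 2 * H, 3 * H))
        o = ad.sigmoid(ad.slice_cols(z, 3 * H, 4 * H))
        c_new = (f * c) + (i * g)
        h_new = o * ad.tanh(c_new)
        if mask is not None:
            m = ad.constant(mask)
            inv = ad.constant(1.0 - mask)
            c_new = (m * c_new) + (inv * c)
            h_new = (m * h_new) + (inv * h)
        return h_new, c_new

    def params(self) -> list[Tensor]:
        return [self.W, self.U, self.b]
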