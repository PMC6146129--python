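"""Optimizers: SGD with per-checkpoint exponential learning-rate decay (used
by the sequence tagger) and RMSProp (used by the relation classifier)."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["SGD", "RMSProp", "clip_global_norm"]


def clip_global_norm(params: list[Tensor], max_norm: float) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 0.05, decay: float = 0.95,
                 clip_norm: float | None = 5.0) -> None:
        self.params = params
        self.lr = lr
        self.decay = decay
        self.clip_norm = clip_norm

    def step(self) -> None:
        if self.clip_norm is not None:
            clip_global_norm(self.params, self.clip_norm)
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def decay_lr(self) -> None:
        """Apply one exponential decay step (called per checkpoint)."""
        self.lr *= self.decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class RMSProp:
    def __init__(self, params: list[Tensor], lr: float = 0.001, rho: float = 0.9,
                 eps: float = 1e-8, clip_norm: float | None = None) -> None:
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.clip_norm = clip_norm
        self.cache = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        if self.clip_norm is not None:
            clip_global_norm(self.params, self.clip_norm)
        for p, c in zip(self.params, self.cache):
            if p.grad is None:
                continue
            c *= self.rho
            c += (1.0 - self.rho) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
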