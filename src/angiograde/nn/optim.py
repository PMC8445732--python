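"""Adam optimizer over the leaf layers of one or more networks."""

from __future__ import annotations

from typing import Iterable, List

import numpy as np

from .layers import Layer


class Adam:
    def __init__(
        self,
        layers: Iterable[Layer],
        lr: float = 2e-3,
        betas=(0.5, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.leaves: List[Layer] = []
        for layer in layers:
            self.leaves.extend(layer.leaves())
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in leaf.params.items()} for leaf in self.leaves
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in leaf.params.items()} for leaf in self.leaves
        ]

    def zero_grad(self) -> None:
        for leaf in self.leaves:
            leaf.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for leaf, m, v in zip(self.leaves, self.m, self.v):
            for k, p in leaf.params.items():
                g = leaf.grads[k]
                m[k] = self.b1 * m[k] + (1.0 - self.b1) * g
                v[k] = self.b2 * v[k] + (1.0 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
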