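"""Loss functions returning (scalar value, gradient w.r.t. the prediction)."""

from __future__ import annotations

from typing import Tuple

import numpy as np

Array = np.ndarray


def mse_loss(pred: Array, target) -> Tuple[float, Array]:
    """Mean squared error; ``target`` may be a scalar (broadcast)."""
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 * diff / diff.size).astype(np.float32)


def l1_loss(pred: Array, target: Array) -> Tuple[float, Array]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), (np.sign(diff) / diff.size).astype(np.float32)


def softmax(logits: Array) -> Array:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Array, labels: Array) -> Tuple[float, Array]:
    """Mean cross-entropy over integer labels; gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + eps)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


def bce_with_logits(logits: Array, targets: Array) -> Tuple[float, Array]:
    """Elementwise binary cross-entropy on logits (numerically stable).

    ``targets`` may be soft (label-smoothed) values in [0, 1].
    """
    t = np.asarray(targets, dtype=np.float32)
    x = logits
    loss = float(np.mean(np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))))
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
    return loss, ((sig - t) / x.size).astype(np.float32)
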