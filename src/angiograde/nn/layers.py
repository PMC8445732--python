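"""Differentiable layers with explicit forward/backward and per-call caches."""

from __future__ import annotations

from typing import Any, Dict, List, Optional, Tuple

import numpy as np

Array = np.ndarray


class Layer:
    """Base class: parameters and their gradient accumulators."""

    def __init__(self) -> None:
        self.params: Dict[str, Array] = {}
        self.grads: Dict[str, Array] = {}

    def forward(self, x: Array) -> Tuple[Array, Any]:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, cache: Any, dy: Array) -> Array:  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def _init_grads(self) -> None:
        self.zero_grad()

    # flat iteration helpers used by optimizers / serialization
    def leaves(self) -> List["Layer"]:
        return [self] if self.params else []


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via im2col, zero padding."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        bias: bool = True,
        init_std: float = 0.05,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        self.params["W"] = rng.normal(0.0, init_std, (out_ch, in_ch, kernel, kernel)).astype(
            np.float32
        )
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self._init_grads()

    def forward(self, x: Array) -> Tuple[Array, Any]:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, ho * wo, c * k * k
        )
        wmat = self.params["W"].reshape(self.out_ch, -1)
        y = cols @ wmat.T
        if "b" in self.params:
            y += self.params["b"]
        out = y.transpose(0, 2, 1).reshape(n, self.out_ch, ho, wo)
        return out.astype(np.float32), (cols, x.shape, (ho, wo))

    def backward(self, cache: Any, dy: Array) -> Array:
        cols, xshape, (ho, wo) = cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dy2 = dy.reshape(n, self.out_ch, ho * wo).transpose(0, 2, 1)  # (n, L, out)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        self.grads["W"] += (
            dy2.reshape(-1, self.out_ch).T @ cols.reshape(-1, c * k * k)
        ).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] += dy.sum(axis=(0, 2, 3))
        dcols = dy2 @ wmat  # (n, L, c*k*k)
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization with affine parameters."""

    def __init__(self, ch: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(ch, dtype=np.float32)
        self.params["beta"] = np.zeros(ch, dtype=np.float32)
        self._init_grads()

    def forward(self, x: Array) -> Tuple[Array, Any]:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        y = self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][
            None, :, None, None
        ]
        return y.astype(np.float32), (xhat, ivar)

    def backward(self, cache: Any, dy: Array) -> Array:
        xhat, ivar = cache
        m = xhat.shape[2] * xhat.shape[3]
        g = self.params["gamma"][None, :, None, None]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        dxhat = dy * g
        # standard normalization backward, per (n, c) slice
        dx = (
            dxhat
            - dxhat.mean(axis=(2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        ) * ivar
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: Array) -> Tuple[Array, Any]:
        m = x > 0
        return x * m, m

    def backward(self, cache: Any, dy: Array) -> Array:
        return dy * cache


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: Array) -> Tuple[Array, Any]:
        m = x > 0
        return np.where(m, x, self.slope * x).astype(np.float32), m

    def backward(self, cache: Any, dy: Array) -> Array:
        return np.where(cache, dy, self.slope * dy).astype(np.float32)


class Tanh(Layer):
    def forward(self, x: Array) -> Tuple[Array, Any]:
        y = np.tanh(x)
        return y.astype(np.float32), y

    def backward(self, cache: Any, dy: Array) -> Array:
        return (dy * (1.0 - cache**2)).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x: Array) -> Tuple[Array, Any]:
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return y.astype(np.float32), y

    def backward(self, cache: Any, dy: Array) -> Array:
        return (dy * cache * (1.0 - cache)).astype(np.float32)


class Upsample2x(Layer):
    """Nearest-neighbour ×2 spatial upsampling."""

    def forward(self, x: Array) -> Tuple[Array, Any]:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3), x.shape

    def backward(self, cache: Any, dy: Array) -> Array:
        n, c, h, w = cache
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)).astype(np.float32)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: Array) -> Tuple[Array, Any]:
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, cache: Any, dy: Array) -> Array:
        n, c, h, w = cache
        return (np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)).astype(
            np.float32
        )


class Linear(Layer):
    def __init__(
        self, d_in: int, d_out: int, rng: Optional[np.random.Generator] = None
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, 1.0 / np.sqrt(d_in), (d_out, d_in)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(d_out, dtype=np.float32)
        self._init_grads()

    def forward(self, x: Array) -> Tuple[Array, Any]:
        return x @ self.params["W"].T + self.params["b"], x

    def backward(self, cache: Any, dy: Array) -> Array:
        self.grads["W"] += dy.T @ cache
        self.grads["b"] += dy.sum(axis=0)
        return (dy @ self.params["W"]).astype(np.float32)


class Sequential(Layer):
    """Chain of layers; the cache is the list of member caches."""

    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Array) -> Tuple[Array, Any]:
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, cache: Any, dy: Array) -> Array:
        for layer, c in zip(reversed(self.layers), reversed(cache)):
            dy = layer.backward(c, dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def leaves(self) -> List[Layer]:
        out: List[Layer] = []
        for layer in self.layers:
            out.extend(layer.leaves())
        return out


class Residual(Layer):
    """y = x + body(x); body must preserve shape."""

    def __init__(self, body: Layer) -> None:
        super().__init__()
        self.body = body

    def forward(self, x: Array) -> Tuple[Array, Any]:
        y, c = self.body.forward(x)
        return x + y, c

    def backward(self, cache: Any, dy: Array) -> Array:
        return dy + self.body.backward(cache, dy)

    def zero_grad(self) -> None:
        self.body.zero_grad()

    def leaves(self) -> List[Layer]:
        return self.body.leaves()
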