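"""Network architectures for the angiography pipeline.

Deliberately small, desk-scale versions of the standard building blocks:
residual generators, patch discriminators, CNN classifiers with global
pooling, and a two-level U-net. Inputs are single-channel images whose side
is divisible by 4.
"""

from __future__ import annotations

from typing import Any, Dict, List, Tuple

import numpy as np

from .layers import (
    Conv2d,
    GlobalAvgPool,
    InstanceNorm2d,
    Layer,
    LeakyReLU,
    Linear,
    ReLU,
    Residual,
    Sequential,
    Sigmoid,
    Upsample2x,
)

Array = np.ndarray


class Network(Sequential):
    """Sequential network with flat state-dict serialization."""

    def state_dict(self) -> Dict[str, Array]:
        out: Dict[str, Array] = {}
        for i, leaf in enumerate(self.leaves()):
            for k, v in leaf.params.items():
                out[f"{i}.{k}"] = v.copy()
        return out

    def load_state_dict(self, state: Dict[str, Array]) -> None:
        for i, leaf in enumerate(self.leaves()):
            for k in leaf.params:
                key = f"{i}.{k}"
                if key not in state:
                    raise KeyError(f"missing parameter {key} in checkpoint")
                if state[key].shape != leaf.params[k].shape:
                    raise ValueError(f"shape mismatch for {key}")
                leaf.params[k] = state[key].astype(np.float32).copy()


def ResnetGenerator(
    rng: np.random.Generator, ngf: int = 8, n_blocks: int = 6
) -> Network:
    """Residual encoder–decoder generator, sigmoid output in [0, 1]."""

    def block(ch: int) -> Residual:
        return Residual(
            Sequential(
                Conv2d(ch, ch, 3, rng=rng),
                InstanceNorm2d(ch),
                ReLU(),
                Conv2d(ch, ch, 3, rng=rng),
                InstanceNorm2d(ch),
            )
        )

    layers: List[Layer] = [
        Conv2d(1, ngf, 7, rng=rng),
        InstanceNorm2d(ngf),
        ReLU(),
        Conv2d(ngf, 2 * ngf, 3, stride=2, rng=rng),
        InstanceNorm2d(2 * ngf),
        ReLU(),
        Conv2d(2 * ngf, 4 * ngf, 3, stride=2, rng=rng),
        InstanceNorm2d(4 * ngf),
        ReLU(),
    ]
    layers += [block(4 * ngf) for _ in range(n_blocks)]
    layers += [
        Upsample2x(),
        Conv2d(4 * ngf, 2 * ngf, 3, rng=rng),
        InstanceNorm2d(2 * ngf),
        ReLU(),
        Upsample2x(),
        Conv2d(2 * ngf, ngf, 3, rng=rng),
        InstanceNorm2d(ngf),
        ReLU(),
        Conv2d(ngf, 1, 7, rng=rng),
        Sigmoid(),
    ]
    return Network(*layers)


def PatchDiscriminator(rng: np.random.Generator, ndf: int = 8) -> Network:
    """3-layer patch discriminator emitting a real/fake score map."""
    return Network(
        Conv2d(1, ndf, 4, stride=2, pad=1, rng=rng),
        LeakyReLU(0.2),
        Conv2d(ndf, 2 * ndf, 4, stride=2, pad=1, rng=rng),
        InstanceNorm2d(2 * ndf),
        LeakyReLU(0.2),
        Conv2d(2 * ndf, 1, 4, stride=1, pad=1, rng=rng),
    )


def CNNClassifier(rng: np.random.Generator, n_out: int, nf: int = 8) -> Network:
    """4-conv classifier with global average pooling; emits logits."""
    return Network(
        Conv2d(1, nf, 3, stride=2, rng=rng),
        LeakyReLU(0.2),
        Conv2d(nf, 2 * nf, 3, stride=2, rng=rng),
        InstanceNorm2d(2 * nf),
        LeakyReLU(0.2),
        Conv2d(2 * nf, 4 * nf, 3, stride=2, rng=rng),
        InstanceNorm2d(4 * nf),
        LeakyReLU(0.2),
        Conv2d(4 * nf, 4 * nf, 3, stride=2, rng=rng),
        InstanceNorm2d(4 * nf),
        LeakyReLU(0.2),
        GlobalAvgPool(),
        Linear(4 * nf, n_out, rng=rng),
    )


class UNet(Layer):
    """Two-level U-net with skip concatenations; emits per-pixel logits."""

    def __init__(self, rng: np.random.Generator, base: int = 8, in_ch: int = 1) -> None:
        super().__init__()
        b = base
        self.enc1 = Sequential(Conv2d(in_ch, b, 3, rng=rng), ReLU(), Conv2d(b, b, 3, rng=rng), ReLU())
        self.down1 = Sequential(Conv2d(b, 2 * b, 3, stride=2, rng=rng), ReLU())
        self.enc2 = Sequential(Conv2d(2 * b, 2 * b, 3, rng=rng), ReLU())
        self.down2 = Sequential(Conv2d(2 * b, 4 * b, 3, stride=2, rng=rng), ReLU())
        self.bott = Sequential(Conv2d(4 * b, 4 * b, 3, rng=rng), ReLU())
        self.up1 = Sequential(Upsample2x(), Conv2d(4 * b, 2 * b, 3, rng=rng), ReLU())
        self.dec2 = Sequential(Conv2d(4 * b, 2 * b, 3, rng=rng), ReLU())
        self.up2 = Sequential(Upsample2x(), Conv2d(2 * b, b, 3, rng=rng), ReLU())
        self.dec1 = Sequential(Conv2d(2 * b, b, 3, rng=rng), ReLU())
        self.head = Conv2d(b, 1, 1, pad=0, rng=rng)
        self._parts = [
            self.enc1, self.down1, self.enc2, self.down2, self.bott,
            self.up1, self.dec2, self.up2, self.dec1, self.head,
        ]

    def forward(self, x: Array) -> Tuple[Array, Any]:
        e1, c1 = self.enc1.forward(x)
        d1, cd1 = self.down1.forward(e1)
        e2, c2 = self.enc2.forward(d1)
        d2, cd2 = self.down2.forward(e2)
        b, cb = self.bott.forward(d2)
        u1, cu1 = self.up1.forward(b)
        f2, cf2 = self.dec2.forward(np.concatenate([u1, e2], axis=1))
        u2, cu2 = self.up2.forward(f2)
        f1, cf1 = self.dec1.forward(np.concatenate([u2, e1], axis=1))
        y, ch = self.head.forward(f1)
        nch1 = u1.shape[1]
        nch2 = u2.shape[1]
        return y, (c1, cd1, c2, cd2, cb, cu1, cf2, cu2, cf1, ch, nch1, nch2)

    def backward(self, cache: Any, dy: Array) -> Array:
        c1, cd1, c2, cd2, cb, cu1, cf2, cu2, cf1, ch, nch1, nch2 = cache
        df1 = self.head.backward(ch, dy)
        dcat2 = self.dec1.backward(cf1, df1)
        du2, de1_skip = dcat2[:, :nch2], dcat2[:, nch2:]
        df2 = self.up2.backward(cu2, du2)
        dcat1 = self.dec2.backward(cf2, df2)
        du1, de2_skip = dcat1[:, :nch1], dcat1[:, nch1:]
        db = self.up1.backward(cu1, du1)
        dd2 = self.bott.backward(cb, db)
        de2 = self.down2.backward(cd2, dd2) + de2_skip
        dd1 = self.enc2.backward(c2, de2)
        de1 = self.down1.backward(cd1, dd1) + de1_skip
        return self.enc1.backward(c1, de1)

    def zero_grad(self) -> None:
        for part in self._parts:
            part.zero_grad()

    def leaves(self) -> List[Layer]:
        out: List[Layer] = []
        for part in self._parts:
            out.extend(part.leaves())
        return out

    def state_dict(self) -> Dict[str, Array]:
        out: Dict[str, Array] = {}
        for i, leaf in enumerate(self.leaves()):
            for k, v in leaf.params.items():
                out[f"{i}.{k}"] = v.copy()
        return out

    def load_state_dict(self, state: Dict[str, Array]) -> None:
        for i, leaf in enumerate(self.leaves()):
            for k in leaf.params:
                leaf.params[k] = state[f"{i}.{k}"].astype(np.float32).copy()
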