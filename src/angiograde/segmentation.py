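"""Nonperfusion and leakage biomarker segmentation.

Nonperfusion (abnormally dark) detection follows a brightness-reasoning
chain. A minimum filter extracts the local low-brightness distribution of
the early-phase frame. A morphological opening (erode then dilate)
suppresses bright thin structures — vessels and focal leakage — whose
brightness would otherwise contaminate the background estimate. Because
grey opening is anti-extensive it cannot restore the perfused brightness
*inside* a dark lesion, so the moderate-brightness perfused reference is
obtained by a robust quadratic illumination-surface fit to the opened image
over the footprint, iteratively trimming dark-outlier (lesion) residuals.
Pixels whose local minimum falls below ``dark_ratio`` times that reference
are suspected nonperfusion; the thresholded minimum map is a dilation of the
sub-threshold set, so it is eroded with the same window to recover lesion
extent (the pair acts as a binary closing).

The agreement (logical AND) of the suspected masks of a real frame and its
fake-normal counterpart forms the pseudo-nonperfusion label, which trains a
small U-net with label smoothing; the refined mask is the thresholded U-net
output.

Leakage (abnormally bright) is segmented by thresholding the real-minus-fake
difference image of the late phase inside the footprint: robust mode
(default) thresholds at median + z·1.4826·MAD of the nonnegative
in-footprint differences, which is insensitive to lesion burden; zscore mode
uses mean + z·std; Otsu operates on the positive values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Dict, List, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters

from . import nn
from .frames import AngioFrame, LesionMasks, Provenance, RetinaGeometry
from .gan import DifferenceImage

__all__ = [
    "SegParams",
    "local_min_map",
    "moderate_baseline",
    "perfused_baseline",
    "suspected_nonperfusion",
    "pseudo_nonperfusion",
    "NPSegmenter",
    "train_np_unet",
    "segment_nonperfusion",
    "leakage_mask",
]


@dataclass
class SegParams:
    """Tunable segmentation parameters.

    ``min_filter_size`` and ``opening_size`` are odd window sizes in pixels;
    the opening must be wider than the minimum filter so vessels wider than
    the dark-map window are still suppressed. ``dark_ratio`` is the
    multiplicative darkness threshold alpha in (0, 1): a pixel is suspected
    nonperfusion when its local minimum is below alpha times the perfused
    reference, a rule invariant to global illumination scaling.
    ``label_smoothing_eps`` softens pseudolabel targets to {eps, 1 - eps}.
    """

    min_filter_size: int = 7
    opening_size: int = 15
    dark_ratio: float = 0.7
    leak_threshold_mode: str = "robust"  # robust | zscore | otsu
    leak_z: float = 2.0
    label_smoothing_eps: float = 0.1
    unet_epochs: int = 25
    unet_lr: float = 3e-3
    unet_base: int = 8
    unet_batch: int = 4
    unet_balance: bool = True  # reweight foreground pixels by rarity
    unet_augment: bool = True  # random flips during training
    unet_ensemble: int = 2  # independently initialized nets, averaged
    unet_tta: bool = True  # average predictions over the 4 flips
    baseline_trim: float = 1.0
    baseline_iters: int = 6

    def __post_init__(self) -> None:
        for name in ("min_filter_size", "opening_size"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and positive, got {v}")
        if not self.min_filter_size < self.opening_size:
            raise ValueError("min_filter_size must be smaller than opening_size")
        if not 0.0 < self.dark_ratio < 1.0:
            raise ValueError("dark_ratio must lie in (0, 1)")
        if not 0.0 <= self.label_smoothing_eps < 0.5:
            raise ValueError("label_smoothing_eps must lie in [0, 0.5)")
        if self.leak_threshold_mode not in ("robust", "zscore", "otsu"):
            raise ValueError("leak_threshold_mode must be 'robust', 'zscore' or 'otsu'")

    def scaled(self, image_size: int, reference_size: int = 128) -> "SegParams":
        """Window sizes rescaled to another image resolution (kept odd)."""
        s = image_size / reference_size
        odd = lambda v: max(int(round(v * s)) | 1, 1)
        out = SegParams(**{**self.__dict__})
        out.min_filter_size = odd(self.min_filter_size)
        out.opening_size = max(odd(self.opening_size), out.min_filter_size + 2)
        return out


def local_min_map(frame: AngioFrame, size: int) -> np.ndarray:
    """Windowed minimum (size x size, edge-replicated borders)."""
    if size < 1 or size % 2 == 0:
        raise ValueError(f"window size must be odd and positive, got {size}")
    return ndimage.minimum_filter(frame.image, size=size, mode="nearest")


def moderate_baseline(frame: AngioFrame, size: int) -> np.ndarray:
    """Morphological opening (erosion then dilation, square element).

    Suppresses bright structures thinner than ``size`` — vessels and focal
    leakage — exposing the moderate-brightness perfused background between
    them.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError(f"window size must be odd and positive, got {size}")
    return ndimage.grey_opening(frame.image, size=(size, size), mode="nearest")


def _fill_outside(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Replace outside-footprint pixels by their nearest in-footprint value."""
    if footprint.all():
        return img
    idx = ndimage.distance_transform_edt(
        ~footprint, return_distances=False, return_indices=True
    )
    return img[tuple(idx)]


def perfused_baseline(
    frame: AngioFrame, geometry: RetinaGeometry, params: SegParams
) -> np.ndarray:
    """Perfused-brightness reference surface.

    Opens the (boundary-filled) frame to remove vessels and leakage, then
    fits a quadratic illumination surface to the opened values over the
    footprint, iteratively discarding pixels more than ``baseline_trim``
    residual standard deviations *below* the fit — i.e. dark lesions — so
    the reference reflects perfused tissue even inside large nonperfused
    regions.
    """
    fp = geometry.footprint
    if not fp.any():
        raise ValueError("empty footprint")
    f = _fill_outside(np.where(fp, frame.image, 0.0), fp)
    opened = ndimage.grey_opening(f, size=(params.opening_size,) * 2, mode="nearest")

    h, w = opened.shape
    yy, xx = np.mgrid[0:h, 0:w]
    u, v = xx.ravel() / w, yy.ravel() / h
    design = np.column_stack([np.ones(h * w), u, v, u**2, v**2, u * v])
    z = opened.ravel()
    use = fp.ravel().copy()
    coef = np.zeros(6)
    for _ in range(max(params.baseline_iters, 1)):
        coef, *_ = np.linalg.lstsq(design[use], z[use], rcond=None)
        res = z - design @ coef
        sigma = float(res[use].std())
        if sigma <= 0:
            break
        use = fp.ravel() & (res > -params.baseline_trim * sigma)
        if not use.any():  # pathological frame: keep last fit
            break
    return (design @ coef).reshape(h, w).astype(np.float32)


def suspected_nonperfusion(
    frame: AngioFrame, geometry: RetinaGeometry, params: SegParams
) -> np.ndarray:
    """Suspected nonperfusion: local minima well below the perfused reference.

    raw = { p : local_min(p) < dark_ratio * baseline(p) }; since the
    thresholded minimum map dilates the true sub-threshold set by the filter
    window, ``raw`` is eroded with the same window before intersecting the
    footprint.
    """
    if frame.image.shape != geometry.footprint.shape:
        raise ValueError("frame and geometry shapes differ")
    fp = geometry.footprint
    if not fp.any():
        raise ValueError("empty footprint")
    f = _fill_outside(np.where(fp, frame.image, 0.0), fp)
    lo = ndimage.minimum_filter(f, size=params.min_filter_size, mode="nearest")
    base = perfused_baseline(frame, geometry, params)
    raw = lo < params.dark_ratio * base
    k = params.min_filter_size
    raw = ndimage.binary_erosion(raw, structure=np.ones((k, k)), border_value=1)
    return raw & fp


def pseudo_nonperfusion(
    real: AngioFrame, fake: AngioFrame, geometry: RetinaGeometry, params: SegParams
) -> np.ndarray:
    """Agreement (AND) of the suspected masks of the real and fake frames."""
    if real.image.shape != fake.image.shape:
        raise ValueError("real and fake frames must share a shape")
    return suspected_nonperfusion(real, geometry, params) & suspected_nonperfusion(
        fake, geometry, params
    )


@dataclass
class NPSegmenter:
    """Trained U-net nonperfusion segmenter (small flip-averaged ensemble)."""

    nets: List[Any]
    loss_trace: List[float]
    params: SegParams

    def predict_proba(self, frame: AngioFrame) -> np.ndarray:
        img = frame.image.astype(np.float32)
        flips = [(False, False)]
        if self.params.unet_tta:
            flips = [(False, False), (True, False), (False, True), (True, True)]
        acc = np.zeros_like(img, dtype=np.float64)
        for net in self.nets:
            for fx, fy in flips:
                v = img[:, ::-1] if fx else img
                v = v[::-1, :] if fy else v
                logits, _ = net.forward(v[None, None])
                p = 1.0 / (1.0 + np.exp(-np.clip(logits[0, 0], -30, 30)))
                p = p[:, ::-1] if fx else p
                p = p[::-1, :] if fy else p
                acc += p
        return (acc / (len(self.nets) * len(flips))).astype(np.float32)

    def state_dict(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for i, net in enumerate(self.nets):
            for k, v in net.state_dict().items():
                out[f"net{i}/{k}"] = v
        return out


def train_np_unet(
    frames: Sequence[AngioFrame],
    pseudolabels: Sequence[np.ndarray],
    params: SegParams,
    seed: int,
) -> NPSegmenter:
    """Train the U-net on pseudolabels with label smoothing.

    Targets are ``1 - eps`` on pseudolabel foreground and ``eps`` elsewhere;
    the loss is per-pixel binary cross-entropy on logits. Because lesion
    pixels are rare, foreground pixels are reweighted by their inverse
    frequency over the training set (``unet_balance``) so the net does not
    collapse to all-background. Training is full-image, one frame per step,
    seeded and reproducible.
    """
    if len(frames) == 0:
        raise ValueError("empty training set")
    if len(frames) != len(pseudolabels):
        raise ValueError("frames and pseudolabels must have equal length")
    eps = params.label_smoothing_eps
    x_all = np.stack([f.image for f in frames])[:, None].astype(np.float32)
    h_all = np.stack([np.asarray(m, dtype=bool) for m in pseudolabels])[:, None]

    pos_weight = 1.0
    if params.unet_balance:
        frac = h_all.sum() / h_all.size
        if 0.0 < frac < 0.5:
            pos_weight = min((1.0 - frac) / frac, 50.0)

    trace: List[float] = []
    nets: List[Any] = []
    n = len(frames)
    bs = max(params.unet_batch, 1)
    for member in range(max(params.unet_ensemble, 1)):
        rng = np.random.default_rng(seed + 7919 * member)
        net = nn.UNet(rng, base=params.unet_base)
        opt = nn.Adam([net], lr=params.unet_lr, betas=(0.9, 0.999))
        for epoch in range(params.unet_epochs):
            if epoch == int(params.unet_epochs * 0.6):
                opt.lr *= 0.3  # late-phase decay stabilizes the small net
            order = rng.permutation(n)
            epoch_loss, n_steps = 0.0, 0
            for s in range(0, n, bs):
                b = order[s : s + bs]
                x, hard = x_all[b].copy(), h_all[b].copy()
                if params.unet_augment:
                    for i in range(len(b)):
                        if rng.random() < 0.5:
                            x[i, 0] = x[i, 0, :, ::-1]
                            hard[i, 0] = hard[i, 0, :, ::-1]
                        if rng.random() < 0.5:
                            x[i, 0] = x[i, 0, ::-1, :]
                            hard[i, 0] = hard[i, 0, ::-1, :]
                t = np.where(hard, 1.0 - eps, eps).astype(np.float32)
                logits, cache = net.forward(x)
                w = np.where(hard, pos_weight, 1.0).astype(np.float32)
                w *= w.size / w.sum()  # keep the mean-loss scale
                elem = (
                    np.maximum(logits, 0) - logits * t + np.log1p(np.exp(-np.abs(logits)))
                )
                loss = float(np.mean(w * elem))
                sig = 1.0 / (1.0 + np.exp(-np.clip(logits, -30, 30)))
                grad = (w * (sig - t) / logits.size).astype(np.float32)
                if not np.isfinite(loss):
                    raise RuntimeError("non-finite U-net training loss")
                opt.zero_grad()
                net.backward(cache, grad)
                opt.step()
                epoch_loss += loss
                n_steps += 1
            trace.append(epoch_loss / n_steps)
        nets.append(net)
    return NPSegmenter(nets=nets, loss_trace=trace, params=params)


def segment_nonperfusion(
    model: NPSegmenter, frame: AngioFrame, geometry: RetinaGeometry
) -> LesionMasks:
    """Refined nonperfusion mask: sigmoid > 0.5, intersected with footprint."""
    proba = model.predict_proba(frame)
    mask = (proba > 0.5) & geometry.footprint
    return LesionMasks(
        nonperfusion=mask,
        leakage=np.zeros_like(mask, dtype=bool),
        provenance=Provenance.REFINED,
    )


def leakage_mask(
    diff: DifferenceImage, geometry: RetinaGeometry, params: SegParams
) -> np.ndarray:
    """Threshold the late-phase anomaly (difference) map inside the footprint.

    robust mode: t = median + leak_z * 1.4826 * MAD over the nonnegative
    in-footprint differences (burden-insensitive); zscore mode: t = mean +
    leak_z * std over all in-footprint differences; otsu mode: Otsu on the
    positive in-footprint values. An all-zero difference yields an empty
    mask.
    """
    vals = diff.values
    if vals.shape != geometry.footprint.shape:
        raise ValueError("difference and footprint shapes differ")
    fp = geometry.footprint
    inside = vals[fp]
    if inside.size == 0 or not np.any(inside != 0):
        return np.zeros_like(fp, dtype=bool)
    if params.leak_threshold_mode == "robust":
        nonneg = inside[inside >= 0]
        med = float(np.median(nonneg))
        mad = float(np.median(np.abs(nonneg - med)))
        t = med + params.leak_z * 1.4826 * mad
    elif params.leak_threshold_mode == "zscore":
        t = float(inside.mean() + params.leak_z * inside.std())
    else:
        pos = inside[inside > 0]
        if pos.size < 2 or np.allclose(pos, pos[0]):
            return np.zeros_like(fp, dtype=bool)
        t = float(filters.threshold_otsu(pos))
    return (vals > t) & fp
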