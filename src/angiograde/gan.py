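"""Joint CycleGAN + CNN-classifier anomaly model.

Two generators translate between the normal domain (G_X: any -> normal) and
the abnormal domain (G_Y: any -> abnormal), each with a patch discriminator.
Cycle-consistency ties the round trips to the inputs at pixel level, and an
identity term keeps same-domain inputs unchanged. Two CNN classifiers are
optimized jointly with the generators on difference (subtraction) images:
C_X grades the signed real − G_X(real) difference into normal / NPDR / PDR,
and C_Y decides biomarker presence from the G_Y-path difference. The
classification terms focus the translation on category-relevant (lesion)
content instead of a global style transfer.

A trained bundle yields: fake-normal images, difference maps that localize
lesions (an approximately all-zero map for normal inputs), and an end-to-end
grader through the G_X -> subtract -> C_X path.

Training alternates generator+classifier updates with discriminator updates;
everything is seeded and reproducible.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .frames import AngioFrame, Grade, Phase

__all__ = [
    "TrainConfig",
    "GanBundle",
    "DifferenceImage",
    "train_joint",
    "fake_normal",
    "difference_image",
    "classify_grade",
    "loss_components",
]


@dataclass
class TrainConfig:
    """Joint-training configuration.

    ``lambda_cyc``, ``lambda_id`` and ``lambda_cls`` weight the cycle,
    identity and classification terms against the adversarial loss.
    ``adv_mode`` selects least-squares (default) or cross-entropy adversarial
    losses. Architecture sizes are desk-scale defaults.
    """

    image_size: int = 64
    epochs: int = 5
    batch_size: int = 4
    lr: float = 2e-3
    clf_lr: float = 1e-2
    clf_steps: int = 2
    clf_finetune_epochs: int = 15
    lambda_cyc: float = 10.0
    lambda_cls: float = 1.0
    lambda_id: float = 5.0
    adv_mode: str = "least-squares"
    ngf: int = 8
    ndf: int = 8
    n_blocks: int = 4
    clf_nf: int = 8
    augment: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name in ("lambda_cyc", "lambda_cls", "lambda_id"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.adv_mode not in ("least-squares", "cross-entropy"):
            raise ValueError("adv_mode must be 'least-squares' or 'cross-entropy'")
        if self.image_size % 4 != 0:
            raise ValueError("image_size must be divisible by 4")


@dataclass
class DifferenceImage:
    """Signed real − fake difference map; bright values flag bright lesions."""

    values: np.ndarray
    phase: Phase

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.phase = Phase(self.phase)


@dataclass
class GanBundle:
    """Trained generators, discriminators and classifiers plus config."""

    g_x: object
    g_y: object
    d_x: object
    d_y: object
    c_x: object
    c_y: object
    config: TrainConfig
    seed: int
    loss_trace: List[Dict[str, float]] = field(default_factory=list)
    trained: bool = False

    _NETS = ("g_x", "g_y", "d_x", "d_y", "c_x", "c_y")

    def save(self, path) -> None:
        """Single-archive checkpoint: config JSON + all weights (zip of .npy)."""
        path = Path(path)
        with zipfile.ZipFile(path, "w") as zf:
            meta = {
                "config": asdict(self.config),
                "seed": self.seed,
                "trained": self.trained,
                "loss_trace": self.loss_trace,
            }
            zf.writestr("meta.json", json.dumps(meta))
            for name in self._NETS:
                for k, v in getattr(self, name).state_dict().items():
                    buf = io.BytesIO()
                    np.save(buf, v)
                    zf.writestr(f"{name}/{k}.npy", buf.getvalue())

    @classmethod
    def load(cls, path) -> "GanBundle":
        path = Path(path)
        with zipfile.ZipFile(path, "r") as zf:
            meta = json.loads(zf.read("meta.json"))
            config = TrainConfig(**meta["config"])
            bundle = _build_bundle(config, int(meta["seed"]))
            bundle.trained = bool(meta["trained"])
            bundle.loss_trace = list(meta["loss_trace"])
            for name in cls._NETS:
                net = getattr(bundle, name)
                state = {}
                prefix = f"{name}/"
                for info in zf.namelist():
                    if info.startswith(prefix) and info.endswith(".npy"):
                        key = info[len(prefix) : -4]
                        state[key] = np.load(io.BytesIO(zf.read(info)))
                net.load_state_dict(state)
        return bundle


def _build_bundle(config: TrainConfig, seed: int) -> GanBundle:
    rng = np.random.default_rng(seed)
    return GanBundle(
        g_x=nn.ResnetGenerator(rng, ngf=config.ngf, n_blocks=config.n_blocks),
        g_y=nn.ResnetGenerator(rng, ngf=config.ngf, n_blocks=config.n_blocks),
        d_x=nn.PatchDiscriminator(rng, ndf=config.ndf),
        d_y=nn.PatchDiscriminator(rng, ndf=config.ndf),
        c_x=nn.CNNClassifier(rng, 3, nf=config.clf_nf),
        c_y=nn.CNNClassifier(rng, 1, nf=config.clf_nf),
        config=config,
        seed=seed,
    )


def _to_batch(frames: Sequence[AngioFrame], size: int) -> np.ndarray:
    out = np.empty((len(frames), 1, size, size), dtype=np.float32)
    for i, f in enumerate(frames):
        img = f.image
        if img.shape != (size, size):
            img = resize(img, (size, size), anti_aliasing=True).astype(np.float32)
        out[i, 0] = img
    return out


def _augment(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random flip, rotation (±15°) and translation (≤10%), per sample."""
    out = batch.copy()
    n, _, h, w = batch.shape
    for i in range(n):
        img = out[i, 0]
        if rng.random() < 0.5:
            img = img[:, ::-1]
        if rng.random() < 0.5:
            img = img[::-1, :]
        angle = rng.uniform(-15.0, 15.0)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        dy, dx = rng.uniform(-0.1, 0.1, 2) * (h, w)
        img = ndimage.shift(img, (dy, dx), order=1, mode="nearest")
        out[i, 0] = img
    return out.astype(np.float32)


def _adv_loss(logits: np.ndarray, real: bool, mode: str) -> Tuple[float, np.ndarray]:
    if mode == "least-squares":
        return nn.mse_loss(logits, 1.0 if real else 0.0)
    target = np.full_like(logits, 1.0 if real else 0.0)
    return nn.bce_with_logits(logits, target)


def train_joint(
    dataset: Sequence[AngioFrame], config: TrainConfig, seed: int
) -> GanBundle:
    """Alternating optimization of (generators + classifiers) and discriminators.

    The dataset is split by label into a normal domain (grade = normal) and
    an abnormal domain (NPDR plus PDR); both phases enter as independent
    samples tagged by phase. Per-epoch means of every loss component are
    recorded in the bundle's ``loss_trace``.
    """
    for f in dataset:
        if f.grade is None:
            raise ValueError("every training frame needs a grade label")
    x_frames = [f for f in dataset if f.grade is Grade.NORMAL]
    y_frames = [f for f in dataset if f.grade is not Grade.NORMAL]
    if not x_frames or not y_frames:
        raise ValueError("need at least one normal-domain and one abnormal-domain frame")

    size = config.image_size
    x_all = _to_batch(x_frames, size)
    y_all = _to_batch(y_frames, size)
    x_grades = np.array([f.grade.ordinal for f in x_frames])
    y_grades = np.array([f.grade.ordinal for f in y_frames])

    rng = np.random.default_rng(seed)
    bundle = _build_bundle(config, seed)
    g_x, g_y = bundle.g_x, bundle.g_y
    d_x, d_y = bundle.d_x, bundle.d_y
    c_x, c_y = bundle.c_x, bundle.c_y
    opt_g = nn.Adam([g_x, g_y], lr=config.lr)
    opt_c = nn.Adam([c_x, c_y], lr=config.clf_lr, betas=(0.9, 0.999))
    opt_d = nn.Adam([d_x, d_y], lr=config.lr)

    lcyc, lid, lcls = config.lambda_cyc, config.lambda_id, config.lambda_cls
    bs = config.batch_size
    n_steps = int(np.ceil(max(len(x_frames), len(y_frames)) / bs))

    for epoch in range(config.epochs):
        sums = {k: 0.0 for k in ("adv", "cyc", "id", "cls", "gen_total", "disc")}
        xi = rng.permutation(len(x_frames))
        yi = rng.permutation(len(y_frames))
        for step in range(n_steps):
            bx = xi[(step * bs + np.arange(bs)) % len(x_frames)]
            by = yi[(step * bs + np.arange(bs)) % len(y_frames)]
            x = x_all[bx]
            y = y_all[by]
            if config.augment:
                x = _augment(x, rng)
                y = _augment(y, rng)
            gx_lab, gy_lab = x_grades[bx], y_grades[by]

            # ---- generators + classifiers -------------------------------
            opt_g.zero_grad()
            opt_c.zero_grad()
            opt_d.zero_grad()

            fake_x, c_gx_y = g_x.forward(y)  # abnormal -> normal
            fake_y, c_gy_x = g_y.forward(x)  # normal -> abnormal
            id_x, c_gx_x = g_x.forward(x)  # identity path, reused for C_X
            id_y, c_gy_y = g_y.forward(y)  # identity path, reused for C_Y

            d_fake_x = np.zeros_like(fake_x)
            d_fake_y = np.zeros_like(fake_y)
            d_id_x = np.zeros_like(id_x)
            d_id_y = np.zeros_like(id_y)

            # adversarial terms (through the frozen-for-now discriminators)
            p_fx, c_dfx = d_x.forward(fake_x)
            l_adv_x, g_adv = _adv_loss(p_fx, True, config.adv_mode)
            d_fake_x += d_x.backward(c_dfx, g_adv)
            p_fy, c_dfy = d_y.forward(fake_y)
            l_adv_y, g_adv = _adv_loss(p_fy, True, config.adv_mode)
            d_fake_y += d_y.backward(c_dfy, g_adv)
            l_adv = l_adv_x + l_adv_y

            # cycle consistency both ways
            rec_y, c_rec_y = g_y.forward(fake_x)
            l_cyc_y, g_cy = nn.l1_loss(rec_y, y)
            d_fake_x += g_y.backward(c_rec_y, lcyc * g_cy)
            rec_x, c_rec_x = g_x.forward(fake_y)
            l_cyc_x, g_cx = nn.l1_loss(rec_x, x)
            d_fake_y += g_x.backward(c_rec_x, lcyc * g_cx)
            l_cyc = l_cyc_x + l_cyc_y

            # identity terms
            l_id_x, g_ix = nn.l1_loss(id_x, x)
            d_id_x += lid * g_ix
            l_id_y, g_iy = nn.l1_loss(id_y, y)
            d_id_y += lid * g_iy
            l_ident = l_id_x + l_id_y

            # classification terms on difference images
            l_cls = 0.0
            if lcls > 0:
                diff_cx = np.concatenate([x - id_x, y - fake_x])
                logits_cx, c_cx = c_x.forward(diff_cx)
                l_cx, g_logits = nn.softmax_cross_entropy(
                    logits_cx, np.concatenate([gx_lab, gy_lab])
                )
                d_diff = c_x.backward(c_cx, lcls * g_logits)
                d_id_x += -d_diff[: len(x)]
                d_fake_x += -d_diff[len(x) :]

                diff_cy = np.concatenate([fake_y - x, id_y - y])
                logits_cy, c_cy = c_y.forward(diff_cy)
                targets = np.concatenate(
                    [np.zeros((len(x), 1)), np.ones((len(y), 1))]
                ).astype(np.float32)
                l_cy, g_logits_y = nn.bce_with_logits(logits_cy, targets)
                d_diff_y = c_y.backward(c_cy, lcls * g_logits_y)
                d_fake_y += d_diff_y[: len(x)]
                d_id_y += d_diff_y[len(x) :]
                l_cls = l_cx + l_cy

            # push accumulated gradients through the generators
            g_x.backward(c_gx_y, d_fake_x)
            g_y.backward(c_gy_x, d_fake_y)
            g_x.backward(c_gx_x, d_id_x)
            g_y.backward(c_gy_y, d_id_y)

            gen_total = l_adv + lcyc * l_cyc + lid * l_ident + lcls * l_cls
            if not np.isfinite(gen_total):
                raise RuntimeError(
                    f"non-finite generator loss at epoch {epoch}: adv={l_adv} "
                    f"cyc={l_cyc} id={l_ident} cls={l_cls}"
                )
            # discriminators accumulated spurious gradients above; drop them
            opt_d.zero_grad()
            opt_g.step()
            opt_c.step()

            # extra classifier-only refreshes on the current difference
            # images (generators frozen): the grading heads need more
            # updates than the slowly-evolving generators provide
            if lcls > 0 and config.clf_steps > 1:
                diff_cx_d = diff_cx.copy()
                diff_cy_d = diff_cy.copy()
                lab_cx = np.concatenate([gx_lab, gy_lab])
                for _ in range(config.clf_steps - 1):
                    opt_c.zero_grad()
                    logits_cx, c_cx2 = c_x.forward(diff_cx_d)
                    _, g2 = nn.softmax_cross_entropy(logits_cx, lab_cx)
                    c_x.backward(c_cx2, g2)
                    logits_cy, c_cy2 = c_y.forward(diff_cy_d)
                    _, g3 = nn.bce_with_logits(logits_cy, targets)
                    c_y.backward(c_cy2, g3)
                    opt_c.step()

            # ---- discriminators -----------------------------------------
            opt_d.zero_grad()
            l_disc = 0.0
            for d_net, real_b, fake_b in ((d_x, x, fake_x), (d_y, y, fake_y)):
                p_r, c_r = d_net.forward(real_b)
                l_r, g_r = _adv_loss(p_r, True, config.adv_mode)
                d_net.backward(c_r, 0.5 * g_r)
                p_f, c_f = d_net.forward(fake_b)  # fake is detached by construction
                l_f, g_f = _adv_loss(p_f, False, config.adv_mode)
                d_net.backward(c_f, 0.5 * g_f)
                l_disc += 0.5 * (l_r + l_f)
            if not np.isfinite(l_disc):
                raise RuntimeError(f"non-finite discriminator loss at epoch {epoch}")
            opt_d.step()

            sums["adv"] += l_adv
            sums["cyc"] += l_cyc
            sums["id"] += l_ident
            sums["cls"] += l_cls
            sums["gen_total"] += gen_total
            sums["disc"] += l_disc

        bundle.loss_trace.append({k: v / n_steps for k, v in sums.items()})

    # final classifier fit with frozen generators: the grading heads are
    # refitted on the converged G_X / G_Y difference images of the whole
    # training set (no augmentation), which stabilizes the end-to-end path
    if lcls > 0 and config.clf_finetune_epochs > 0:
        allx = np.concatenate([x_all, y_all])
        labels = np.concatenate([x_grades, y_grades])
        fake_all, _ = g_x.forward(allx)
        diff_x_all = allx - fake_all
        gen_y_all, _ = g_y.forward(allx)
        diff_y_all = gen_y_all - allx
        bin_targets = (labels > 0).astype(np.float32)[:, None]
        n = len(allx)
        for _ in range(config.clf_finetune_epochs):
            order = rng.permutation(n)
            for s in range(0, n, 8):
                b = order[s : s + 8]
                opt_c.zero_grad()
                logits, cc = c_x.forward(diff_x_all[b])
                loss_x, g = nn.softmax_cross_entropy(logits, labels[b])
                c_x.backward(cc, g)
                logits_y, cy = c_y.forward(diff_y_all[b])
                loss_y, gy2 = nn.bce_with_logits(logits_y, bin_targets[b])
                c_y.backward(cy, gy2)
                if not (np.isfinite(loss_x) and np.isfinite(loss_y)):
                    raise RuntimeError("non-finite classifier fine-tune loss")
                opt_c.step()

    bundle.trained = True
    return bundle


def loss_components(
    bundle: GanBundle,
    x: np.ndarray,
    y: np.ndarray,
    x_labels: np.ndarray,
    y_labels: np.ndarray,
) -> Dict[str, float]:
    """Evaluate every joint-loss component on fixed batches, no updates.

    ``x`` / ``y`` are (N, 1, H, W) normal- / abnormal-domain batches. Returns
    the unweighted components plus the weighted ``gen_total``; useful for
    checking that the joint objective decomposes into its independently
    computed terms.
    """
    cfg = bundle.config
    fake_x, _ = bundle.g_x.forward(y)
    fake_y, _ = bundle.g_y.forward(x)
    id_x, _ = bundle.g_x.forward(x)
    id_y, _ = bundle.g_y.forward(y)
    l_adv = (
        _adv_loss(bundle.d_x.forward(fake_x)[0], True, cfg.adv_mode)[0]
        + _adv_loss(bundle.d_y.forward(fake_y)[0], True, cfg.adv_mode)[0]
    )
    l_cyc = (
        nn.l1_loss(bundle.g_y.forward(fake_x)[0], y)[0]
        + nn.l1_loss(bundle.g_x.forward(fake_y)[0], x)[0]
    )
    l_ident = nn.l1_loss(id_x, x)[0] + nn.l1_loss(id_y, y)[0]
    l_cls = 0.0
    if cfg.lambda_cls > 0:
        logits_cx, _ = bundle.c_x.forward(np.concatenate([x - id_x, y - fake_x]))
        l_cx, _ = nn.softmax_cross_entropy(
            logits_cx, np.concatenate([x_labels, y_labels])
        )
        logits_cy, _ = bundle.c_y.forward(np.concatenate([fake_y - x, id_y - y]))
        targets = np.concatenate(
            [np.zeros((len(x), 1)), np.ones((len(y), 1))]
        ).astype(np.float32)
        l_cy, _ = nn.bce_with_logits(logits_cy, targets)
        l_cls = l_cx + l_cy
    return {
        "adv": l_adv,
        "cyc": l_cyc,
        "id": l_ident,
        "cls": l_cls,
        "gen_total": l_adv
        + cfg.lambda_cyc * l_cyc
        + cfg.lambda_id * l_ident
        + cfg.lambda_cls * l_cls,
    }


def _require_trained(bundle: GanBundle) -> None:
    if not bundle.trained:
        raise ValueError("bundle is untrained; call train_joint or load a checkpoint")


def fake_normal(bundle: GanBundle, frame: AngioFrame) -> AngioFrame:
    """Translate a frame into the normal domain with G_X.

    Input is resampled to the training resolution if needed and the output
    resampled back, so the result matches the input shape; values stay in
    [0, 1] by construction (sigmoid output).
    """
    _require_trained(bundle)
    size = bundle.config.image_size
    orig_shape = frame.image.shape
    x = _to_batch([frame], size)
    y, _ = bundle.g_x.forward(x)
    out = y[0, 0]
    if out.shape != orig_shape:
        out = resize(out, orig_shape, anti_aliasing=True).astype(np.float32)
    return frame.with_image(np.clip(out, 0.0, 1.0))


def difference_image(real: AngioFrame, fake: AngioFrame) -> DifferenceImage:
    """Signed pixelwise real − fake map (bright lesions positive)."""
    if real.image.shape != fake.image.shape:
        raise ValueError("real and fake frames must share a shape")
    return DifferenceImage(values=real.image - fake.image, phase=real.phase)


def classify_grade(bundle: GanBundle, frame: AngioFrame) -> np.ndarray:
    """End-to-end grading through G_X -> subtract -> C_X.

    Returns the softmax probability triple over (normal, NPDR, PDR).
    """
    _require_trained(bundle)
    size = bundle.config.image_size
    x = _to_batch([frame], size)
    fake, _ = bundle.g_x.forward(x)
    logits, _ = bundle.c_x.forward(x - fake)
    return nn.softmax(logits)[0]
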