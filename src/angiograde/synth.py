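"""Synthetic ultra-widefield angiogram phantom generator.

Real UWFA cohorts are private clinical data, so every stage of the pipeline
is exercised on seeded synthetic eyes with known ground truth. A scene is an
elliptical visible-retina footprint on a dark background carrying a branching
bright vessel tree and a smooth illumination falloff. Lesions are planted
with known masks:

* nonperfusion — dark patches (local intensity multiplied by a factor in
  [0.2, 0.5]) rendered in both phases, detected from the early phase;
* leakage — bright blobs added in the late phase only;
* microaneurysms — 1–3 px bright dots in both phases, folded into the
  leakage (bright-biomarker) truth mask.

Rendered brightness obeys the clinical ordering: leakage > vessels ≥
perfused background > nonperfusion.

Every eye comes with a lesion-free twin of the identical scene (same vessels,
illumination and noise realisation), which serves as a ground-truth
"fake normal" oracle: late − late_clean is the exact leakage rendering and
early − early_clean is the exact nonperfusion darkening.

Lesion-burden defaults increase strictly from normal through NPDR to PDR, so
planted index statistics are monotone in grade by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .frames import (
    AngioFrame,
    Grade,
    LesionMasks,
    Phase,
    Provenance,
    RetinaGeometry,
)

__all__ = [
    "SceneParams",
    "SyntheticEye",
    "PlacementError",
    "params_for_grade",
    "generate_eye",
    "generate_dataset",
    "GRADE_DEFAULTS",
]


class PlacementError(ValueError):
    """Requested lesion area cannot be placed inside the allowed region."""


#: Grade-conditional lesion-burden defaults (area fractions of the footprint
#: and microaneurysm counts). Strictly ordered normal < NPDR < PDR.
GRADE_DEFAULTS: Dict[Grade, Dict[str, float]] = {
    Grade.NORMAL: {"np_area_fraction": 0.0, "lk_area_fraction": 0.0, "ma_count": 0},
    Grade.NPDR: {"np_area_fraction": 0.07, "lk_area_fraction": 0.05, "ma_count": 8},
    Grade.PDR: {"np_area_fraction": 0.20, "lk_area_fraction": 0.14, "ma_count": 16},
}


@dataclass
class SceneParams:
    """Parameters of one synthetic eye.

    ``footprint_axes`` are the ellipse semi-axes in pixels (default scales
    with ``image_size``). ``disc_macula_frac`` is the disc–macula distance as
    a fraction of the image width; it also sets the 7-standard-field radius
    downstream. ``peripheral_only`` restricts lesion placement to the region
    farther than three disc–macula distances from the macula, guaranteeing no
    overlap with the 7-standard-field circles.
    """

    image_size: int = 128
    footprint_axes: Optional[Tuple[float, float]] = None
    vessel_count: int = 5
    illumination_gradient: float = 0.35
    np_area_fraction: float = 0.0
    lk_area_fraction: float = 0.0
    ma_count: int = 0
    grade: Grade = Grade.NORMAL
    seed: int = 0
    disc_macula_frac: float = 0.15
    peripheral_only: bool = False
    noise_sigma: float = 0.02
    blob_scale: float = 0.08  # lesion-blob correlation length, fraction of size

    def __post_init__(self) -> None:
        self.grade = Grade(self.grade)
        if self.footprint_axes is None:
            self.footprint_axes = (0.45 * self.image_size, 0.38 * self.image_size)
        for name in ("np_area_fraction", "lk_area_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5], got {v}")
        if self.grade is Grade.NORMAL and (
            self.np_area_fraction > 0 or self.lk_area_fraction > 0 or self.ma_count > 0
        ):
            raise ValueError("normal eyes carry no lesions: fractions and ma_count must be 0")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32 pixels")
        if self.vessel_count < 1:
            raise ValueError("vessel_count must be positive")


def params_for_grade(grade: Grade, *, image_size: int = 128, seed: int = 0, **overrides) -> SceneParams:
    """Scene parameters with the grade-conditional lesion-burden defaults."""
    grade = Grade(grade)
    kwargs = dict(GRADE_DEFAULTS[grade])
    kwargs["ma_count"] = int(kwargs["ma_count"])
    kwargs.update(overrides)
    return SceneParams(image_size=image_size, grade=grade, seed=seed, **kwargs)


@dataclass
class SyntheticEye:
    """A generated eye: lesion frames, clean twins, geometry and truth masks."""

    early: AngioFrame
    late: AngioFrame
    early_clean: AngioFrame
    late_clean: AngioFrame
    geometry: RetinaGeometry
    truth_masks: LesionMasks
    grade: Grade
    params: SceneParams
    eye_id: str = "eye"

    @property
    def planted_indices(self) -> Tuple[float, float]:
        """(ischemic, leakage) area fractions of the planted masks."""
        d2 = float(self.geometry.footprint.sum())
        return (
            float(self.truth_masks.nonperfusion.sum()) / d2,
            float(self.truth_masks.leakage.sum()) / d2,
        )


# ---------------------------------------------------------------------------
# scene rendering helpers
# ---------------------------------------------------------------------------

def _ellipse_mask(size: int, center: Tuple[float, float], axes: Tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cx, cy = center
    a, b = axes
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _illumination(size: int, center: Tuple[float, float], axes: Tuple[float, float], slope: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cx, cy = center
    a, b = axes
    rho2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    return (1.0 - slope * np.clip(rho2, 0.0, 1.0)).astype(np.float32)


def _draw_vessel_tree(
    size: int,
    rng: np.random.Generator,
    root: Tuple[float, float],
    n_trunks: int,
    footprint: np.ndarray,
) -> np.ndarray:
    """Anti-aliased coverage map (0..1) of a recursive branching tree."""
    from skimage.draw import line_aa

    canvas = np.zeros((size, size), dtype=np.float32)

    def draw_segment(x0: float, y0: float, angle: float, length: float, depth: int) -> None:
        if depth <= 0 or length < 2:
            return
        x1 = x0 + length * np.cos(angle)
        y1 = y0 + length * np.sin(angle)
        r0, c0 = int(round(y0)), int(round(x0))
        r1, c1 = int(round(np.clip(y1, 0, size - 1))), int(round(np.clip(x1, 0, size - 1)))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        np.maximum.at(canvas, (rr[keep], cc[keep]), val[keep].astype(np.float32))
        spread = rng.uniform(0.35, 0.65)
        for sign in (-1.0, 1.0):
            draw_segment(
                x1,
                y1,
                angle + sign * spread + rng.normal(0.0, 0.1),
                length * rng.uniform(0.6, 0.8),
                depth - 1,
            )

    x0, y0 = root
    base = rng.uniform(0.0, 2.0 * np.pi)
    for i in range(n_trunks):
        angle = base + 2.0 * np.pi * i / n_trunks + rng.normal(0.0, 0.15)
        draw_segment(x0, y0, angle, 0.28 * size * rng.uniform(0.8, 1.2), depth=5)

    canvas *= footprint
    return np.clip(canvas, 0.0, 1.0)


def _blob_mask(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n_pixels: int,
    sigma: float,
) -> np.ndarray:
    """Random smooth-blob mask of exactly ``n_pixels`` pixels inside ``allowed``.

    A Gaussian-smoothed noise field is thresholded at the quantile that yields
    the requested pixel count, so the planted area fraction is exact up to
    rounding. Raises :class:`PlacementError` when the allowed region is too
    small.
    """
    if n_pixels == 0:
        return np.zeros_like(allowed, dtype=bool)
    n_allowed = int(allowed.sum())
    if n_pixels > n_allowed:
        raise PlacementError(
            f"cannot place {n_pixels} lesion pixels inside a region of {n_allowed} pixels"
        )
    fld = ndimage.gaussian_filter(rng.normal(size=allowed.shape), sigma=sigma)
    vals = fld[allowed]
    # threshold picked so exactly n_pixels allowed pixels exceed it
    cut = np.partition(vals, n_allowed - n_pixels)[n_allowed - n_pixels]
    mask = np.zeros_like(allowed, dtype=bool)
    inside = fld >= cut
    mask[allowed & inside] = True
    # ties at the cut can overshoot by a few pixels; trim deterministically
    excess = int(mask.sum()) - n_pixels
    if excess > 0:
        idx = np.flatnonzero(mask.ravel() & (fld.ravel() == cut))[:excess]
        mask.ravel()[idx] = False
    return mask


def _dot_mask(
    rng: np.random.Generator, allowed: np.ndarray, count: int, radius: int = 1
) -> np.ndarray:
    """Mask of ``count`` small round dots at random allowed positions."""
    mask = np.zeros_like(allowed, dtype=bool)
    if count == 0:
        return mask
    ys, xs = np.nonzero(allowed)
    if len(ys) == 0:
        raise PlacementError("no room for microaneurysm dots")
    pick = rng.choice(len(ys), size=min(count, len(ys)), replace=False)
    size = allowed.shape[0]
    yy, xx = np.mgrid[0:allowed.shape[0], 0:allowed.shape[1]]
    for k in pick:
        cy, cx = ys[k], xs[k]
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return mask & allowed


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_eye(params: SceneParams, eye_id: str = "eye") -> SyntheticEye:
    """Render one synthetic eye (deterministic for a fixed seed).

    Returns lesion frames, the lesion-free twins of the identical scene
    (same vessels and the same noise realisation per phase), the planted
    geometry and the planted truth masks.
    """
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    axes = params.footprint_axes
    assert axes is not None

    footprint = _ellipse_mask(size, center, axes)
    if not footprint.any():
        raise PlacementError("footprint ellipse is empty")
    illum = _illumination(size, center, axes, params.illumination_gradient)

    macula = center
    disc = (center[0] - params.disc_macula_frac * size, center[1])
    vessels = _draw_vessel_tree(size, rng, disc, params.vessel_count, footprint)

    # clean scene: dark outside footprint, moderate perfused background,
    # bright vessels; identical in both phases
    background = np.where(footprint, 0.45 * illum, 0.02).astype(np.float32)
    vessel_value = (0.78 * illum).astype(np.float32)
    clean = background * (1.0 - vessels) + vessel_value * vessels
    vessel_mask = vessels > 0.5

    # planted lesions
    n_fp = int(footprint.sum())
    sigma = params.blob_scale * size
    if params.peripheral_only:
        r = params.disc_macula_frac * size
        yy, xx = np.mgrid[0:size, 0:size]
        far = (xx - macula[0]) ** 2 + (yy - macula[1]) ** 2 > (3.0 * r) ** 2
        allowed = footprint & far
    else:
        allowed = footprint.copy()

    np_mask = _blob_mask(rng, allowed, int(round(params.np_area_fraction * n_fp)), sigma)
    lk_allowed = allowed & ~np_mask
    lk_mask = _blob_mask(rng, lk_allowed, int(round(params.lk_area_fraction * n_fp)), sigma)
    ma_mask = _dot_mask(rng, lk_allowed & ~lk_mask & ~vessel_mask, params.ma_count)
    bright_mask = lk_mask | ma_mask  # microaneurysms join the bright-biomarker channel

    # nonperfusion: multiplicative darkening, factor in [0.2, 0.5]
    darkening = np.ones((size, size), dtype=np.float32)
    if np_mask.any():
        u = ndimage.gaussian_filter(rng.random((size, size)), sigma=sigma)
        u = (u - u.min()) / max(float(np.ptp(u)), 1e-9)
        darkening[np_mask] = (0.2 + 0.3 * u[np_mask]).astype(np.float32)

    early_lesion = clean * np.where(np_mask, darkening, 1.0)
    late_lesion = early_lesion.copy()

    # leakage: additive bright bump confined to its mask, late phase only
    if lk_mask.any():
        bump = ndimage.gaussian_filter(lk_mask.astype(np.float32), sigma=max(sigma / 2, 1.0))
        bump /= max(bump.max(), 1e-9)
        late_lesion = late_lesion + (0.5 * (0.35 + 0.65 * bump)).astype(np.float32) * lk_mask

    # microaneurysm dots: bright in both phases
    if ma_mask.any():
        early_lesion = np.where(ma_mask, np.maximum(early_lesion, 0.85 * illum), early_lesion)
        late_lesion = np.where(ma_mask, np.maximum(late_lesion, 0.88 * illum), late_lesion)

    # shared per-phase noise so the clean twin is an exact oracle
    noise_early = rng.normal(0.0, params.noise_sigma, (size, size)).astype(np.float32)
    noise_late = rng.normal(0.0, params.noise_sigma, (size, size)).astype(np.float32)

    def finish(img: np.ndarray, noise: np.ndarray) -> np.ndarray:
        return np.clip(img + noise, 0.0, 1.0).astype(np.float32)

    frames = {}
    for name, img, phase, noise in (
        ("early", early_lesion, Phase.EARLY, noise_early),
        ("late", late_lesion, Phase.LATE, noise_late),
        ("early_clean", clean, Phase.EARLY, noise_early),
        ("late_clean", clean, Phase.LATE, noise_late),
    ):
        frames[name] = AngioFrame(
            image=finish(img, noise),
            phase=phase,
            disc_xy=disc,
            macula_xy=macula,
            grade=params.grade,
            eye_id=eye_id,
        )

    geometry = RetinaGeometry(footprint=footprint, disc_xy=disc, macula_xy=macula)
    truth = LesionMasks(nonperfusion=np_mask, leakage=bright_mask, provenance=Provenance.PLANTED)
    return SyntheticEye(
        early=frames["early"],
        late=frames["late"],
        early_clean=frames["early_clean"],
        late_clean=frames["late_clean"],
        geometry=geometry,
        truth_masks=truth,
        grade=params.grade,
        params=params,
        eye_id=eye_id,
    )


def generate_dataset(
    n_normal: int,
    n_npdr: int,
    n_pdr: int,
    seed: int,
    *,
    image_size: int = 128,
    jitter: float = 0.3,
    **overrides,
) -> List[SyntheticEye]:
    """Generate a graded cohort of synthetic eyes.

    Per-eye seeds are derived from the master seed. ``jitter`` scales a
    multiplicative spread applied to each eye's lesion-burden defaults so
    grades form clusters rather than three identical burdens; the
    grade-conditional means stay strictly ordered.
    """
    for name, n in (("n_normal", n_normal), ("n_npdr", n_npdr), ("n_pdr", n_pdr)):
        if n < 0:
            raise ValueError(f"{name} must be nonnegative")
    master = np.random.default_rng(seed)
    grades = (
        [Grade.NORMAL] * n_normal + [Grade.NPDR] * n_npdr + [Grade.PDR] * n_pdr
    )
    eyes: List[SyntheticEye] = []
    for i, grade in enumerate(grades):
        eye_seed = int(master.integers(0, 2**31 - 1))
        factor_np = float(np.clip(1.0 + jitter * master.standard_normal(), 0.4, 1.6))
        factor_lk = float(np.clip(1.0 + jitter * master.standard_normal(), 0.4, 1.6))
        base = GRADE_DEFAULTS[grade]
        ov = dict(overrides)
        if grade is Grade.NORMAL:
            for key in ("np_area_fraction", "lk_area_fraction", "ma_count"):
                ov.pop(key, None)
        else:
            ov.setdefault("np_area_fraction", min(base["np_area_fraction"] * factor_np, 0.5))
            ov.setdefault("lk_area_fraction", min(base["lk_area_fraction"] * factor_lk, 0.5))
        params = params_for_grade(grade, image_size=image_size, seed=eye_seed, **ov)
        eyes.append(generate_eye(params, eye_id=f"eye{i:03d}"))
    return eyes
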