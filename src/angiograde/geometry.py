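"""Visible-retina footprint, the normalization standard d², and the
simulated ETDRS 7-standard-field mask.

The ischemic and leakage indices are lesion areas divided by the biological
standard d², taken here as the pixel count (area) of the visible retina, so
both indices are dimensionless area fractions in [0, 1].

The 7-standard-field (7-SF) grid is built from the two expert landmarks:
field 1 is centered on the optic disc, field 2 on the macula, and fields 3–7
form a tangent ring at twice the field radius from the macula (field 3
temporal, the rest at ±60° and ±120° from the macula→temporal axis). The
field radius equals the disc–macula distance. Masked 7-SF images keep the
full-field d² so that index differences between UWFA and 7-SF reflect lesion
area lost outside the posterior pole.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from skimage import filters
from skimage.morphology import convex_hull_image

from .frames import AngioFrame, RetinaGeometry

__all__ = [
    "FieldMask",
    "FootprintError",
    "DegenerateGeometryError",
    "detect_footprint",
    "compute_d2",
    "build_7sf_mask",
    "apply_mask",
]


class FootprintError(ValueError):
    """No visible-retina footprint could be found."""


class DegenerateGeometryError(ValueError):
    """Landmarks do not define a usable 7-SF layout."""


@dataclass
class FieldMask:
    """Union of the seven circular standard fields."""

    mask: np.ndarray
    field_centers: List[Tuple[float, float]]
    field_radius: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.field_centers) != 7:
            raise ValueError("a 7-standard-field mask needs exactly 7 field centers")
        if self.field_radius <= 0:
            raise ValueError("field radius must be positive")


def detect_footprint(frame: AngioFrame) -> np.ndarray:
    """Detect the visible-retina footprint of an angiogram frame.

    Thresholds the image automatically, keeps the largest connected
    component and fills its holes. Because dark lesions inside the retina can
    sit far below the perfused brightness, a three-class multi-Otsu split is
    used and the *lowest* threshold (device background vs any tissue) taken;
    plain Otsu would cut through dark nonperfusion instead. Raises
    :class:`FootprintError` when the image carries no foreground at all.
    """
    img = np.asarray(frame.image, dtype=np.float32)
    if img.size == 0:
        raise FootprintError("empty image")
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-6:
        if hi <= 1e-6:
            raise FootprintError("all-dark image: no visible retina")
        return np.ones_like(img, dtype=bool)  # uniformly bright frame
    try:
        t = float(filters.threshold_multiotsu(img, classes=3)[0])
    except ValueError:  # fewer than 3 distinct grey levels
        t = float(filters.threshold_otsu(img))
    fg = img > t
    if not fg.any():
        raise FootprintError("no pixels above the background threshold")
    fg = ndimage.binary_closing(fg, structure=np.ones((3, 3)))
    labels, n = ndimage.label(fg)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        fg = labels == (int(np.argmax(counts)) + 1)
    # dark lesions touching the rim cut bays into the threshold mask; the
    # visible-retina footprint is convex (elliptical), so close them with
    # the convex hull rather than hole filling alone
    return convex_hull_image(fg)


def compute_d2(footprint: np.ndarray) -> float:
    """The normalization standard d²: the visible-retina area in pixels."""
    fp = np.asarray(footprint, dtype=bool)
    area = float(fp.sum())
    if area <= 0:
        raise FootprintError("empty footprint has no area")
    return area


def build_7sf_mask(geometry: RetinaGeometry) -> FieldMask:
    """Construct the simulated ETDRS 7-standard-field mask from landmarks.

    Field radius r = disc–macula distance. Field 1 sits on the disc, field 2
    on the macula, field 3 at 2r from the macula along the macula→temporal
    direction (opposite the disc), and fields 4–7 at 2r from the macula at
    ±60° and ±120° from that axis. The union of the seven circles is
    intersected with the footprint. Pixels whose centers fall within a circle
    (inclusive boundary) belong to the field.
    """
    disc = np.asarray(geometry.disc_xy, dtype=float)
    macula = np.asarray(geometry.macula_xy, dtype=float)
    dm = disc - macula
    r = float(np.hypot(*dm))
    if r < 1e-9:
        raise DegenerateGeometryError("disc and macula landmarks coincide")
    temporal = -dm / r  # away from the disc

    centers = [tuple(disc), tuple(macula)]
    for deg in (0.0, 60.0, -60.0, 120.0, -120.0):
        th = np.deg2rad(deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        centers.append(tuple(macula + 2.0 * r * (rot @ temporal)))

    h, w = geometry.footprint.shape
    yy, xx = np.mgrid[0:h, 0:w]
    union = np.zeros((h, w), dtype=bool)
    for cx, cy in centers:
        union |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return FieldMask(mask=union & geometry.footprint, field_centers=centers, field_radius=r)


def apply_mask(frame: AngioFrame, field: FieldMask) -> AngioFrame:
    """Zero out pixels outside the field mask; landmarks are preserved."""
    if frame.image.shape != field.mask.shape:
        raise ValueError(
            f"frame shape {frame.image.shape} does not match mask shape {field.mask.shape}"
        )
    return frame.with_image(np.where(field.mask, frame.image, 0.0))
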