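"""Core domain containers for ultra-widefield angiography analysis.

An eye contributes two grayscale frames: an early-phase frame (dye transit,
used for nonperfusion / the ischemic index) and a late-phase frame (dye
leakage, used for the leakage index). Frames carry the optic-disc and macula
landmarks and, for labelled data, a three-level diabetic-retinopathy grade
(normal, NPDR, PDR).

Intensities are floats in [0, 1] in memory; on disk frames are 8-bit PNG.
Coordinates are 0-based ``(x, y)`` with x = column, y = row.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "Grade",
    "Phase",
    "Provenance",
    "AngioFrame",
    "RetinaGeometry",
    "LesionMasks",
    "IndexPair",
    "GRADES",
]


class Grade(str, enum.Enum):
    """Diabetic-retinopathy severity grade."""

    NORMAL = "normal"
    NPDR = "NPDR"
    PDR = "PDR"

    @property
    def ordinal(self) -> int:
        return GRADES.index(self)


GRADES: Tuple[Grade, Grade, Grade] = (Grade.NORMAL, Grade.NPDR, Grade.PDR)


class Phase(str, enum.Enum):
    """Angiographic phase tag (timing semantics are out of scope)."""

    EARLY = "early"
    LATE = "late"


class Provenance(str, enum.Enum):
    """How a lesion mask was obtained."""

    PLANTED = "planted"
    SUSPECTED = "suspected"
    PSEUDO = "pseudo"
    REFINED = "refined"


@dataclass
class AngioFrame:
    """One grayscale angiogram frame.

    Parameters
    ----------
    image : float array in [0, 1], shape (H, W)
    phase : early or late
    disc_xy, macula_xy : optic-disc / macula landmark, (x, y) pixels, or None
    grade : DR grade label if known
    eye_id : identifier tying the frame to its eye
    """

    image: np.ndarray
    phase: Phase
    disc_xy: Optional[Tuple[float, float]] = None
    macula_xy: Optional[Tuple[float, float]] = None
    grade: Optional[Grade] = None
    eye_id: Optional[str] = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=np.float32)
        if img.ndim != 2:
            raise ValueError(f"frame image must be 2-D grayscale, got shape {img.shape}")
        self.image = img
        self.phase = Phase(self.phase)
        if self.grade is not None:
            self.grade = Grade(self.grade)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]

    def with_image(self, image: np.ndarray) -> "AngioFrame":
        """Copy of this frame with a replacement pixel array, landmarks kept."""
        return replace(self, image=np.asarray(image, dtype=np.float32))


@dataclass
class RetinaGeometry:
    """Visible-retina footprint plus landmarks and the normalization standard.

    ``d2`` is the biological standard used to normalize lesion areas into
    indices: here the pixel count of the visible-retina footprint, so that
    the ischemic and leakage indices are dimensionless area fractions.
    A masked (7-standard-field) geometry may carry the *full-field* d2 with
    a restricted footprint, so that masked indices remain comparable.
    """

    footprint: np.ndarray
    disc_xy: Tuple[float, float]
    macula_xy: Tuple[float, float]
    d2: Optional[float] = None

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint)
        if fp.ndim != 2:
            raise ValueError("footprint must be a 2-D mask")
        self.footprint = fp.astype(bool)
        if self.d2 is None:
            self.d2 = float(self.footprint.sum())
        if self.d2 <= 0:
            raise ValueError("d2 must be positive (empty footprint?)")

    def restricted(self, mask: np.ndarray) -> "RetinaGeometry":
        """Geometry with footprint intersected by ``mask`` but d2 unchanged."""
        return RetinaGeometry(
            footprint=self.footprint & np.asarray(mask, dtype=bool),
            disc_xy=self.disc_xy,
            macula_xy=self.macula_xy,
            d2=self.d2,
        )


@dataclass
class LesionMasks:
    """Binary nonperfusion and leakage masks with provenance."""

    nonperfusion: np.ndarray
    leakage: np.ndarray
    provenance: Provenance

    def __post_init__(self) -> None:
        self.nonperfusion = np.asarray(self.nonperfusion, dtype=bool)
        self.leakage = np.asarray(self.leakage, dtype=bool)
        self.provenance = Provenance(self.provenance)
        if self.nonperfusion.shape != self.leakage.shape:
            raise ValueError("nonperfusion and leakage masks must share a shape")


@dataclass(frozen=True)
class IndexPair:
    """(ischemic index, leakage index) — dimensionless lesion-area fractions."""

    ischemic_index: float
    leakage_index: float

    def as_array(self) -> np.ndarray:
        return np.array([self.ischemic_index, self.leakage_index], dtype=float)
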