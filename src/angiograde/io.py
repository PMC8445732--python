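"""Readers and writers: frames (PNG/TIFF grayscale), binary masks, and the
dataset manifest (CSV).

Frames are stored 8-bit (or 16-bit TIFF) grayscale and mapped to floats in
[0, 1]; round trips at the stored bit depth are lossless. Masks are strict
0/255 PNG; any other value is rejected. The manifest is one CSV row per eye
carrying paths, landmarks, grade, seed, and (as stages run) fold ids,
indices and predictions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .frames import AngioFrame, Grade, LesionMasks, Phase, Provenance, RetinaGeometry
from .synth import SyntheticEye

__all__ = [
    "IOError_",
    "NonBinaryMaskError",
    "ManifestError",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_manifest",
    "validate_manifest",
    "write_dataset",
    "load_eye",
]


class IOError_(ValueError):
    """Unreadable or unsupported image input."""


class NonBinaryMaskError(IOError_):
    """A mask file contained values other than {0, 255}."""


class ManifestError(ValueError):
    """Manifest fails validation."""


def _read_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise IOError_(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise IOError_(f"{path}: expected 2-D grayscale, got shape {arr.shape}")
    return arr


def read_image(
    path,
    phase: Phase = Phase.EARLY,
    disc_xy=None,
    macula_xy=None,
    grade: Optional[Grade] = None,
    eye_id: Optional[str] = None,
) -> AngioFrame:
    """Read an 8- or 16-bit grayscale frame into a [0, 1] float image."""
    path = Path(path)
    arr = _read_array(path)
    if arr.dtype == np.uint8:
        img = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        img = arr.astype(np.float32) / 65535.0
    else:
        raise IOError_(f"{path}: unsupported dtype {arr.dtype} (need uint8/uint16)")
    return AngioFrame(
        image=img, phase=phase, disc_xy=disc_xy, macula_xy=macula_xy,
        grade=grade, eye_id=eye_id,
    )


def write_image(frame: AngioFrame, path, bit_depth: int = 8) -> None:
    """Write a frame as grayscale PNG (8-bit) or TIFF (8- or 16-bit)."""
    path = Path(path)
    img = np.clip(frame.image, 0.0, 1.0)
    if bit_depth == 8:
        arr = np.rint(img * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.rint(img * 65535.0).astype(np.uint16)
    else:
        raise IOError_("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        if bit_depth != 8:
            raise IOError_("PNG output is 8-bit; use TIFF for 16-bit")
        Image.fromarray(arr, mode="L").save(path)


def read_mask(path) -> np.ndarray:
    """Read a strict 0/255 PNG mask as a boolean array."""
    arr = _read_array(Path(path))
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 255))):
        raise NonBinaryMaskError(
            f"{path}: mask values must be exactly 0 or 255, found {vals[:10]}"
        )
    return arr == 255


def write_mask(mask: np.ndarray, path) -> None:
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


MANIFEST_COLUMNS = [
    "eye_id", "grade", "seed",
    "early_path", "late_path", "early_clean_path", "late_clean_path",
    "footprint_path", "np_mask_path", "lk_mask_path",
    "disc_x", "disc_y", "macula_x", "macula_y",
]


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_manifest(df, base=Path(path).parent, check_files=True)
    return df


def validate_manifest(df: pd.DataFrame, base=None, check_files: bool = False) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    dupes = df["eye_id"][df["eye_id"].duplicated()].tolist()
    if dupes:
        raise ManifestError(f"duplicate eye_id values: {dupes}")
    bad = sorted(set(df["grade"]) - {g.value for g in Grade})
    if bad:
        raise ManifestError(f"unknown grades: {bad}")
    if check_files and base is not None:
        for col in ("early_path", "late_path", "early_clean_path", "late_clean_path",
                    "footprint_path", "np_mask_path", "lk_mask_path"):
            for p in df[col]:
                if not (Path(base) / str(p)).exists():
                    raise ManifestError(f"referenced file does not exist: {p}")


def write_dataset(eyes: Sequence[SyntheticEye], outdir) -> pd.DataFrame:
    """Write per-eye PNG frames and masks plus the manifest CSV.

    Paths in the manifest are relative to ``outdir``; returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: List[Dict] = []
    for eye in eyes:
        d = outdir / eye.eye_id
        d.mkdir(exist_ok=True)
        rel = lambda name: f"{eye.eye_id}/{name}"
        write_image(eye.early, d / "early.png")
        write_image(eye.late, d / "late.png")
        write_image(eye.early_clean, d / "early_clean.png")
        write_image(eye.late_clean, d / "late_clean.png")
        write_mask(eye.geometry.footprint, d / "footprint.png")
        write_mask(eye.truth_masks.nonperfusion, d / "np_mask.png")
        write_mask(eye.truth_masks.leakage, d / "lk_mask.png")
        rows.append({
            "eye_id": eye.eye_id,
            "grade": eye.grade.value,
            "seed": eye.params.seed,
            "early_path": rel("early.png"),
            "late_path": rel("late.png"),
            "early_clean_path": rel("early_clean.png"),
            "late_clean_path": rel("late_clean.png"),
            "footprint_path": rel("footprint.png"),
            "np_mask_path": rel("np_mask.png"),
            "lk_mask_path": rel("lk_mask.png"),
            "disc_x": eye.geometry.disc_xy[0],
            "disc_y": eye.geometry.disc_xy[1],
            "macula_x": eye.geometry.macula_xy[0],
            "macula_y": eye.geometry.macula_xy[1],
        })
    df = pd.DataFrame(rows)
    validate_manifest(df)
    write_manifest(df, outdir / "manifest.csv")
    return df


def load_eye(row, base) -> SyntheticEye:
    """Reconstruct a SyntheticEye from one manifest row."""
    from .synth import SceneParams  # local: avoid cycle at import time

    base = Path(base)
    grade = Grade(row["grade"])
    disc = (float(row["disc_x"]), float(row["disc_y"]))
    macula = (float(row["macula_x"]), float(row["macula_y"]))
    meta = dict(disc_xy=disc, macula_xy=macula, grade=grade, eye_id=row["eye_id"])
    early = read_image(base / row["early_path"], Phase.EARLY, **meta)
    late = read_image(base / row["late_path"], Phase.LATE, **meta)
    early_clean = read_image(base / row["early_clean_path"], Phase.EARLY, **meta)
    late_clean = read_image(base / row["late_clean_path"], Phase.LATE, **meta)
    footprint = read_mask(base / row["footprint_path"])
    geometry = RetinaGeometry(footprint=footprint, disc_xy=disc, macula_xy=macula)
    truth = LesionMasks(
        nonperfusion=read_mask(base / row["np_mask_path"]),
        leakage=read_mask(base / row["lk_mask_path"]),
        provenance=Provenance.PLANTED,
    )
    size = early.image.shape[0]
    params = SceneParams(image_size=size, grade=grade, seed=int(row["seed"])) \
        if grade is Grade.NORMAL else SceneParams(
            image_size=size, grade=grade, seed=int(row["seed"]),
            np_area_fraction=0.1, lk_area_fraction=0.1)
    return SyntheticEye(
        early=early, late=late, early_clean=early_clean, late_clean=late_clean,
        geometry=geometry, truth_masks=truth, grade=grade, params=params,
        eye_id=str(row["eye_id"]),
    )
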