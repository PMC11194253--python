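"""Cervical-vertebrae ROI cropping and normalization.

The crop runs vertically from the Basion landmark down to the inferior
border of C4, horizontally a symmetric window centered on the landmarks'
mean column with half-width ``lateral_margin_frac x vertical extent``.
The crop is resampled to 64x64 and min-max rescaled to [0, 1]; no
smoothing, sharpening or histogram filtering is applied.

Coordinate convention: image origin top-left, row index increases
downward; landmark points are (x, y) = (column, row).  Crop boxes are
reported inclusive as (top, bottom, left, right).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from skimage.transform import resize

from .imageio_utils import read_png, write_png
from .types import Point, RoiImage, StageLabel

logger = logging.getLogger(__name__)

ROI_SIZE = (64, 64)
_MIN_SOURCE_ROWS = 8


class OutOfBoundsError(ValueError):
    pass


class DegenerateCropError(ValueError):
    pass


def _normalize(crop: np.ndarray) -> np.ndarray:
    """Per-crop min-max rescale to [0,1]; a constant crop maps to all-zero."""
    lo, hi = float(crop.min()), float(crop.max())
    if hi - lo <= 0:
        return np.zeros_like(crop)
    return (crop - lo) / (hi - lo)


def extract_roi(
    image: np.ndarray,
    basion: Point,
    c4_inferior: Point,
    lateral_margin_frac: float = 0.5,
    stage_label: StageLabel = StageLabel.UNLABELED,
    source: Tuple[str, int] = ("", -1),
    interpolation: str = "bilinear",
) -> RoiImage:
    """Crop the vertebral column between Basion and the C4 inferior border.

    Parameters
    ----------
    image : 2-D array of intensities (any numeric range).
    basion, c4_inferior : (x, y) pixel landmarks; Basion must lie strictly
        above C4 (smaller row index).
    lateral_margin_frac : half-width of the horizontal window as a fraction
        of the vertical extent.
    interpolation : "bilinear" (default) or "nearest" (the order-preserving
        subsampling oracle used in tests).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D grayscale, got shape {img.shape}")
    H, W = img.shape
    bx, by = float(basion[0]), float(basion[1])
    cx, cy = float(c4_inferior[0]), float(c4_inferior[1])
    for x, y, name in ((bx, by, "basion"), (cx, cy, "c4_inferior")):
        if not (0 <= x < W and 0 <= y < H):
            raise OutOfBoundsError(f"{name} ({x}, {y}) outside image {W}x{H}")
    if not by < cy:
        raise ValueError("basion must lie strictly above c4_inferior")

    top = int(np.floor(by))
    bottom = int(np.ceil(cy))
    extent = bottom - top + 1
    if extent < _MIN_SOURCE_ROWS:
        raise DegenerateCropError(
            f"vertical extent {extent} rows < minimum {_MIN_SOURCE_ROWS}"
        )
    center_col = (bx + cx) / 2.0
    half = lateral_margin_frac * extent
    left = int(np.floor(center_col - half))
    right = int(np.ceil(center_col + half))
    left = max(left, 0)
    right = min(right, W - 1)
    if right <= left:
        raise DegenerateCropError("horizontal extent collapsed after clipping")

    crop = img[top : bottom + 1, left : right + 1]
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    resampled = resize(
        crop, ROI_SIZE, order=order, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return RoiImage(
        pixels=_normalize(resampled),
        stage_label=stage_label,
        source=source,
        crop_box=(top, bottom, left, right),
    )


def recrop_from_box(
    image: np.ndarray,
    crop_box: Tuple[int, int, int, int],
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Reproduce an ROI's pixels from its recorded inclusive crop box."""
    top, bottom, left, right = crop_box
    crop = np.asarray(image, dtype=np.float64)[top : bottom + 1, left : right + 1]
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    return _normalize(
        resize(crop, ROI_SIZE, order=order, mode="edge",
               anti_aliasing=False, preserve_range=True)
    )


ROI_MANIFEST_COLUMNS = [
    "subject_id", "film_index", "roi_path", "stage_label",
    "crop_top", "crop_bottom", "crop_left", "crop_right", "status",
]


def batch_extract(
    manifest: pd.DataFrame,
    out_dir: Optional[Path | str] = None,
    lateral_margin_frac: float = 0.5,
) -> Tuple[List[RoiImage], pd.DataFrame]:
    """Extract one ROI per eligible labeled manifest row.

    Expects columns: image_path, basion_x, basion_y, c4inf_x, c4inf_y, and
    optionally subject_id, film_index, stage_label, quality_ok.  Rows with
    ``quality_ok`` false are skipped (mirroring the study's quality
    exclusions); unreadable files are logged per-row and the run continues.
    """
    rois: List[RoiImage] = []
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for idx, r in manifest.reset_index(drop=True).iterrows():
        sid = str(r.get("subject_id", f"row{idx}"))
        fidx = int(r.get("film_index", idx))
        stage = (
            StageLabel.from_string(str(r["stage_label"]))
            if "stage_label" in manifest.columns and pd.notna(r["stage_label"])
            else StageLabel.UNLABELED
        )
        base = {
            "subject_id": sid, "film_index": fidx, "roi_path": "",
            "stage_label": stage.short,
            "crop_top": -1, "crop_bottom": -1, "crop_left": -1, "crop_right": -1,
        }
        if "quality_ok" in manifest.columns and not bool(r["quality_ok"]):
            logger.info("skipping %s film %d: flagged quality_ok=false", sid, fidx)
            rows.append({**base, "status": "skipped-quality"})
            continue
        try:
            img = read_png(r["image_path"])
            roi = extract_roi(
                img,
                basion=(float(r["basion_x"]), float(r["basion_y"])),
                c4_inferior=(float(r["c4inf_x"]), float(r["c4inf_y"])),
                lateral_margin_frac=lateral_margin_frac,
                stage_label=stage,
                source=(sid, fidx),
            )
        except Exception as exc:  # per-row failure, run continues
            logger.warning("failed on %s film %d: %s", sid, fidx, exc)
            rows.append({**base, "status": f"failed:{type(exc).__name__}"})
            continue
        path = ""
        if out is not None:
            path = str(out / f"{sid}_f{fidx:02d}.png")
            write_png(path, roi.pixels)
        top, bottom, left, right = roi.crop_box  # type: ignore[misc]
        rows.append({
            **base, "roi_path": path, "status": "ok",
            "crop_top": top, "crop_bottom": bottom,
            "crop_left": left, "crop_right": right,
        })
        rois.append(roi)
    roi_manifest = pd.DataFrame(rows, columns=ROI_MANIFEST_COLUMNS)
    if out is not None:
        roi_manifest.to_csv(out / "roi_manifest.csv", index=False)
    return rois, roi_manifest
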