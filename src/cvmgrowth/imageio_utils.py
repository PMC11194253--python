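"""8-bit grayscale PNG read/write helpers (intensities in [0, 1])."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


def write_png(path: Path | str, pixels: np.ndarray) -> None:
    """Write a [0,1] float image as an 8-bit grayscale PNG."""
    arr = np.asarray(pixels, dtype=np.float64)
    u8 = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), u8, extension=".png")


def read_png(path: Path | str) -> np.ndarray:
    """Read an image file as a [0,1] float grayscale array."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:  # collapse any color/alpha channels
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)
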