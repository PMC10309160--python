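"""Readers/writers for masks (8-bit PNG/TIFF), contour CSVs and results."""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .shapes import BinaryMask, Contour

__all__ = [
    "read_mask",
    "write_mask",
    "read_contour_csv",
    "write_contour_csv",
]

log = logging.getLogger("fazmetrics")


def read_mask(path: str | Path) -> BinaryMask:
    """Read a single-channel mask image; foreground is any value > 0."""
    img = iio.imread(path)
    if img.ndim == 3:  # RGB(A): collapse, warn — masks should be 1-channel
        log.warning("%s has %d channels; using the maximum across channels",
                    path, img.shape[2])
        img = img.max(axis=2)
    vals = np.unique(img)
    if len(vals) > 2:
        log.warning("%s is not binary (%d distinct values); thresholding at > 0",
                    path, len(vals))
    return BinaryMask(img > 0)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a mask as 8-bit 0/255."""
    iio.imwrite(path, (mask.grid.astype(np.uint8) * 255))


def read_contour_csv(path: str | Path) -> Contour:
    """Read a contour from a two-column `x,y` CSV with a header row."""
    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise ValueError(f"{path}: contour CSV needs 'x' and 'y' columns")
    return Contour(df[["x", "y"]].to_numpy(dtype=float))


def write_contour_csv(path: str | Path, contour: Contour) -> None:
    pd.DataFrame(contour.vertices, columns=["x", "y"]).to_csv(
        path, index=False, float_format="%.12g"
    )
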