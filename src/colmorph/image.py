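"""AFM height images and their file formats.

An AFM topograph is a raster of heights in nanometres together with the
lateral sampling step (nm per pixel).  Coordinates follow the raster
convention used throughout the package: origin at the top-left pixel, x
rightward along columns, y downward along rows, and a pixel's nominal
position is its *centre*, so pixel (row r, col c) sits at
``((c + 0.5) * pixel_size, (r + 0.5) * pixel_size)`` in nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class AFMImage:
    """A 2-D height field in nm with its pixel size in nm/px."""

    heights: np.ndarray
    pixel_size: float
    id: str = "image"

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(width, height) of the field of view in nm."""
        nrow, ncol = self.heights.shape
        return ncol * self.pixel_size, nrow * self.pixel_size

    def rot90(self) -> "AFMImage":
        """Counter-clockwise quarter-turn copy (the 90-degree scan of a pair)."""
        return AFMImage(np.rot90(self.heights).copy(), self.pixel_size,
                        id=f"{self.id}_rot90")


def pixels_to_nm(rows: np.ndarray, cols: np.ndarray, pixel_size: float) -> np.ndarray:
    """Map integer pixel indices to (x, y) nm at pixel centres."""
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    return np.column_stack([(cols + 0.5) * pixel_size, (rows + 0.5) * pixel_size])


def rotate_points_90(points: np.ndarray, width_nm: float) -> np.ndarray:
    """Transform nm coordinates under the image's counter-clockwise quarter turn.

    Matches ``np.rot90`` on the raster under the pixel-centre convention:
    (x, y) -> (y, width_nm - x), with *width_nm* the original image width.
    """
    pts = np.asarray(points, dtype=float)
    return np.column_stack([pts[:, 1], width_nm - pts[:, 0]])


def write_afm_tiff(image: AFMImage, path: str | Path) -> None:
    """Write a float32 TIFF; pixel size stored in the XResolution tag (px/nm)."""
    res = 1.0 / image.pixel_size
    tifffile.imwrite(
        str(path),
        image.heights.astype(np.float32),
        resolution=(res, res),
        metadata={"pixel_size_nm": image.pixel_size, "id": image.id},
    )


def read_afm_tiff(path: str | Path, pixel_size: float | None = None,
                  id: str | None = None) -> AFMImage:
    """Read a float TIFF heightmap.

    ``pixel_size`` overrides anything stored in the file; if absent from both,
    a ValueError is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        heights = tf.asarray().astype(float)
        stored = None
        try:
            meta = tf.shaped_metadata
            if meta and "pixel_size_nm" in meta[0]:
                stored = float(meta[0]["pixel_size_nm"])
        except (AttributeError, KeyError, TypeError, IndexError):
            stored = None
    px = pixel_size if pixel_size is not None else stored
    if px is None:
        raise ValueError(f"{path}: pixel size not stored in file; pass pixel_size")
    return AFMImage(heights, px, id=id or path.stem)


def read_afm_text(path: str | Path, pixel_size: float,
                  id: str | None = None) -> AFMImage:
    """Read a plain-text numeric matrix (whitespace- or comma-separated nm)."""
    path = Path(path)
    try:
        heights = np.loadtxt(path)
    except ValueError:
        heights = np.loadtxt(path, delimiter=",")
    return AFMImage(np.atleast_2d(heights), pixel_size, id=id or path.stem)
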