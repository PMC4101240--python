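"""Image and level-set data model, file I/O, and zero-contour extraction.

Conventions used throughout the package (fixed here, once):

* coordinates are 0-based ``(row, col)``; the row index increases downward;
* images are normalized to [0, 1] at load time so that every scale and
  threshold parameter transfers across 8- and 16-bit inputs;
* the level set ``phi`` has interior ``{phi < 0}``, exterior ``{phi > 0}``;
  the contour is its zero set.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import measure
from skimage.draw import polygon2mask

__all__ = [
    "Contour",
    "load_grayscale_image",
    "load_mask",
    "save_mask_png",
    "default_sigma",
    "extract_zero_contour",
    "mask_to_contours",
    "rasterize_contours",
    "contours_to_csv",
]

MIN_DIM = 3  # finite differences need interior points


@dataclass
class Contour:
    """An ordered polyline of sub-pixel (row, col) points; a discrete contour."""

    points: np.ndarray  # (n, 2) float array
    closed: bool

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if self.closed and len(self.points) < 3:
            raise ValueError("a closed contour needs at least 3 points")

    def __len__(self) -> int:
        return len(self.points)


def _normalize01(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    lo, hi = float(pixels.min()), float(pixels.max())
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValueError("image contains non-finite intensities")
    if hi == lo:  # constant image: degenerate range maps to all zeros
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def load_grayscale_image(path) -> np.ndarray:
    """Read a PNG/TIFF as a float image linearly rescaled to [0, 1].

    RGB(A) inputs are converted by averaging the color channels (angiography
    sources are often saved as RGB). A constant image maps to all zeros.
    """
    pixels = iio.imread(Path(path))
    if pixels.ndim == 3:
        pixels = np.asarray(pixels, dtype=float)[..., :3].mean(axis=-1)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError(f"expected a 2-D image, got shape {pixels.shape}")
    if pixels.shape[0] < MIN_DIM or pixels.shape[1] < MIN_DIM:
        raise ValueError(f"image too small: {pixels.shape} (need >= {MIN_DIM} per axis)")
    return _normalize01(pixels)


def load_mask(path) -> np.ndarray:
    """Read a binary mask PNG (any nonzero value counts as foreground)."""
    pixels = iio.imread(Path(path))
    if pixels.ndim == 3:
        pixels = pixels[..., :3].max(axis=-1)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError(f"expected a 2-D mask, got shape {pixels.shape}")
    return np.asarray(pixels) > 0


def save_mask_png(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    mask = np.asarray(mask)
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def default_sigma(dim_y: int, dim_x: int) -> int:
    """Default localization-kernel scale: round((dim_y + dim_x) / 16), >= 1.

    One uniform rule tying the kernel size to the image size, so the local
    window covers a comparable image fraction across datasets.
    """
    if dim_y < MIN_DIM or dim_x < MIN_DIM:
        raise ValueError(f"image dims must be >= {MIN_DIM}, got ({dim_y}, {dim_x})")
    value = (dim_y + dim_x) / 16.0
    return max(1, int(math.floor(value + 0.5)))  # round half up, deterministically


def extract_zero_contour(phi: np.ndarray) -> list[Contour]:
    """Sub-pixel polylines of the zero set of ``phi``.

    Uses marching squares (linear interpolation of sign changes between
    4-neighbors). Returns an empty list when ``phi`` does not change sign.
    """
    phi = np.asarray(phi, dtype=float)
    if not (np.any(phi < 0) and np.any(phi > 0)):
        return []  # no zero crossing to trace
    raw = measure.find_contours(phi, level=0.0)
    contours = []
    for pts in raw:
        closed = bool(len(pts) > 1 and np.allclose(pts[0], pts[-1]))
        if closed:
            pts = pts[:-1]
        if (closed and len(pts) < 3) or len(pts) < 2:
            continue  # zero-thickness sliver along exact-zero pixels
        contours.append(Contour(points=pts, closed=closed))
    return contours


def mask_to_contours(mask: np.ndarray) -> list[Contour]:
    """Trace the boundary of a binary mask the same way as a level set.

    The mask is embedded as a +/-1 field so that truth and prediction
    boundaries are extracted by the identical sub-pixel procedure.
    """
    mask = np.asarray(mask, dtype=bool)
    field = np.where(mask, -1.0, 1.0)
    return extract_zero_contour(field)


def rasterize_contours(contours: list[Contour], shape: tuple[int, int]) -> np.ndarray:
    """Union of the regions enclosed by the closed contours (pixel-center test)."""
    out = np.zeros(shape, dtype=bool)
    for c in contours:
        if c.closed:
            out |= polygon2mask(shape, c.points)
    return out


def contours_to_csv(path, contours: list[Contour]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["component", "row", "col"])
        for i, c in enumerate(contours):
            for r, col in c.points:
                writer.writerow([i, f"{r:.4f}", f"{col:.4f}"])
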