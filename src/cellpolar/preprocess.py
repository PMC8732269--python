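"""Preprocessing: projection, neighbor removal, nucleus-center location.

The quantification operates on a single summed-intensity projection of a
confocal z-stack, together with three binary masks: the nucleus, the cell
outline, and an exclusion mask marking signal from neighboring cells that
must be removed before any radial statistics are computed.

Coordinates are 0-based (row, col) with the pixel-center convention: pixel
(i, j) is centered at exactly (i, j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, UsageError

__all__ = [
    "ImagePlane",
    "CellMasks",
    "sum_project",
    "exclude_neighbors",
    "locate_center",
]


@dataclass
class ImagePlane:
    """A single 2D fluorescence image.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Nonnegative float intensities.
    pixel_size : float
        Physical pixel size in micrometers per pixel.
    provenance : str
        Free text describing projection method / channel.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise UsageError(f"image must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise UsageError("image contains non-finite values")
        if np.any(self.pixels < 0):
            raise UsageError("image contains negative intensities")
        if self.pixel_size <= 0:
            raise UsageError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def total_intensity(self) -> float:
        return float(self.pixels.sum())


@dataclass
class CellMasks:
    """Binary masks defining the geometric frame of a single cell.

    ``nucleus`` must be contained in ``cell``; ``exclusion`` marks neighbor
    signal and must not touch the nucleus.  ``center`` is the subpixel
    nucleus center (row, col); if None it is derived by
    :func:`locate_center`.
    """

    nucleus: np.ndarray
    cell: np.ndarray
    exclusion: np.ndarray
    center: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.nucleus = np.asarray(self.nucleus, dtype=bool)
        self.cell = np.asarray(self.cell, dtype=bool)
        self.exclusion = np.asarray(self.exclusion, dtype=bool)
        if not (self.nucleus.shape == self.cell.shape == self.exclusion.shape):
            raise UsageError("mask shapes differ")
        if np.any(self.nucleus & ~self.cell):
            raise UsageError("nucleus mask is not contained in cell mask")
        if np.any(self.nucleus & self.exclusion):
            raise UsageError("exclusion mask overlaps the nucleus")


def sum_project(stack: np.ndarray, pixel_size: float = 1.0,
                provenance: str = "sum projection") -> ImagePlane:
    """Sum a z-stack into a single floating-point plane.

    No clipping or integer rounding is applied; the sum is carried in
    float64 regardless of the input dtype.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise UsageError(f"stack must be 3D with >=1 plane, got shape {stack.shape}")
    return ImagePlane(stack.sum(axis=0, dtype=np.float64), pixel_size=pixel_size,
                      provenance=provenance)


def exclude_neighbors(image: ImagePlane, masks: CellMasks) -> ImagePlane:
    """Zero out pixels under the exclusion mask.

    Removes the signal of neighboring cells so it cannot contribute to the
    radial statistics of the analyzed cell.  Excluded pixels are set to 0
    (not flagged missing); if the exclusion mask overlaps the analyzed
    cell's periphery this slightly deflates peripheral mass.
    """
    if masks.exclusion.shape != image.pixels.shape:
        raise UsageError("exclusion mask shape does not match image")
    out = image.pixels.copy()
    out[masks.exclusion] = 0.0
    return ImagePlane(out, pixel_size=image.pixel_size,
                      provenance=image.provenance + " | neighbors excluded")


def locate_center(masks: CellMasks,
                  override: tuple[float, float] | None = None) -> tuple[float, float]:
    """Locate the nucleus center.

    Returns ``override`` verbatim when given.  Otherwise the
    intensity-unweighted centroid of the nucleus mask is used; if the
    centroid falls outside a (non-convex) nucleus mask a
    :class:`DegenerateGeometryError` asks for a manual override.
    """
    if override is not None:
        return (float(override[0]), float(override[1]))
    rows, cols = np.nonzero(masks.nucleus)
    if rows.size == 0:
        raise DegenerateGeometryError("nucleus mask is empty")
    center = (float(rows.mean()), float(cols.mean()))
    ir, ic = int(round(center[0])), int(round(center[1]))
    if not masks.nucleus[ir, ic]:
        raise DegenerateGeometryError(
            f"nucleus centroid {center} falls outside the nucleus mask "
            "(non-convex nucleus?); supply a manual center override")
    return center
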