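"""File-format plumbing: TIFF/PNG images and masks, polar-map export,
boundary CSVs.

Images are written as 32-bit float TIFF; masks as 8-bit (0/255) TIFF or
PNG.  Polar maps export as float TIFF matrices (rows = angles) with a
JSON sidecar holding the grid metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import UsageError
from .polar import BoundaryRadii, NormalizedPolarMap, PolarMap
from .preprocess import CellMasks, ImagePlane


def read_image(path: str | Path, pixel_size: float = 1.0) -> ImagePlane:
    """Read a single-plane TIFF/PNG image; multi-page TIFFs are rejected
    (sum-project them first with :func:`read_stack`)."""
    arr = _read_array(path)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise UsageError(f"{path}: expected a single 2D plane, got shape {arr.shape}")
    return ImagePlane(np.asarray(arr, dtype=np.float64), pixel_size=pixel_size,
                      provenance=str(path))


def read_stack(path: str | Path) -> np.ndarray:
    """Read a (possibly multi-page) TIFF stack as a 3D array."""
    arr = _read_array(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise UsageError(f"{path}: expected 2D or 3D data, got shape {arr.shape}")
    return arr


def _read_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise UsageError(f"file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            return np.asarray(tifffile.imread(path))
        return np.asarray(iio.imread(path))
    except UsageError:
        raise
    except Exception as exc:
        raise UsageError(f"cannot read image {path}: {exc}") from exc


def write_image(path: str | Path, image: ImagePlane) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def read_mask(path: str | Path) -> np.ndarray:
    arr = _read_array(path)
    if arr.ndim == 3:
        arr = arr[..., 0] if arr.shape[-1] in (3, 4) else arr[0]
    return np.asarray(arr) > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask, bool).astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    else:
        iio.imwrite(str(path), arr)


def load_masks(nucleus: str | Path, cell: str | Path,
               exclusion: str | Path | None = None) -> CellMasks:
    nuc = read_mask(nucleus)
    cel = read_mask(cell)
    exc = read_mask(exclusion) if exclusion else np.zeros_like(nuc)
    return CellMasks(nucleus=nuc, cell=cel, exclusion=exc)


def export_polar_map(pmap: PolarMap | NormalizedPolarMap,
                     path: str | Path) -> None:
    """Write a polar/normalized map as float TIFF + JSON grid sidecar."""
    path = Path(path)
    tifffile.imwrite(str(path), pmap.values.astype(np.float32))
    if isinstance(pmap, NormalizedPolarMap):
        meta = {"kind": "normalized", "u_min": float(pmap.u[0]),
                "u_max": float(pmap.u[-1]), "u_step": pmap.u_step}
    else:
        meta = {"kind": "polar", "r_max": pmap.r_max,
                "radial_step_px": pmap.radial_step_px,
                "theta_step_deg": pmap.theta_step_deg}
    meta.update({"n_theta": int(pmap.theta.size), "center": list(pmap.center),
                 "pixel_size": pmap.pixel_size, "rows": "angles"})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def export_boundary_radii(radii: BoundaryRadii, path: str | Path) -> None:
    pd.DataFrame({
        "theta_deg": np.rad2deg(radii.theta),
        "r_ne_px": radii.r_ne,
        "r_edge_px": radii.r_edge,
    }).to_csv(path, index=False, float_format="%.4f")
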