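"""Polar resampling about the nucleus center and per-angle radial
normalization.

The sweep draws a ray from the nucleus center out past the furthest point
of the cell and rotates it through 360 degrees in small angular steps
(default 0.1 degrees), taking a bilinearly interpolated line profile at
each angle.  Two corrections resolve the mismatch between square pixels
and polar sampling: subpixel bilinear interpolation along each ray, and
Jacobian area weights w = r * dtheta * dr so that weighted polar sums
estimate Cartesian integrals (intensity is conserved through the
transform).

Per angle, the radius where the nuclear envelope sits and the radius where
the cell edge sits define a normalized radial coordinate u:

    u = 100 * (r - r_ne) / (r_edge - r_ne)   for r >= r_ne  (cytoplasm 0..100)
    u =  25 * (r / r_ne - 1)                 for r <  r_ne  (nucleoplasm -25..0)

so cells of different size and shape become commensurable.  The
nucleoplasm band is a control region; in this 2D projection it also
contains cytoplasm and nuclear envelope lying above and below the nucleus.

Angle convention: theta = 0 along the +column axis, increasing with
atan2(row - center_row, col - center_col); coordinates are 0-based with
the pixel-center convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DegenerateGeometryError, UsageError
from .preprocess import CellMasks, ImagePlane

__all__ = [
    "PolarMap",
    "BoundaryRadii",
    "NormalizedPolarMap",
    "sweep_polar",
    "boundary_radii",
    "normalize_radial",
    "U_MIN",
    "U_MAX",
]

U_MIN = -25.0
U_MAX = 100.0
R_MAX_MARGIN_PX = 2.0   # "past the furthest point on the cell"


@dataclass
class PolarMap:
    """Fluorescence resampled on an (angle, radius) grid.

    ``values[i, j]`` is the interpolated intensity at angle ``theta[i]``
    and radius ``radii[j]``; ``area_weight[i, j]`` is the effective
    Cartesian area of that sample, r * dtheta * dr, so that
    ``(area_weight * values).sum()`` estimates the Cartesian total
    intensity.
    """

    values: np.ndarray          # (n_theta, n_r)
    theta: np.ndarray           # radians, (n_theta,)
    radii: np.ndarray           # pixels, (n_r,)
    theta_step_deg: float
    radial_step_px: float
    r_max: float
    center: tuple[float, float]
    pixel_size: float

    @property
    def area_weight(self) -> np.ndarray:
        dtheta = np.deg2rad(self.theta_step_deg)
        w = self.radii * dtheta * self.radial_step_px
        return np.broadcast_to(w, self.values.shape)

    def weighted_total(self) -> float:
        return float((self.area_weight * self.values).sum())


@dataclass
class BoundaryRadii:
    """Per-angle radii of the nuclear envelope and the cell edge."""

    theta: np.ndarray           # radians, (n_theta,)
    r_ne: np.ndarray            # pixels
    r_edge: np.ndarray          # pixels

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.r_ne)) and np.all(np.isfinite(self.r_edge))):
            raise DegenerateGeometryError("non-finite boundary radius")
        bad = np.nonzero(~(self.r_ne > 0) | ~(self.r_edge > self.r_ne))[0]
        if bad.size:
            ang = np.rad2deg(self.theta[bad[0]])
            raise DegenerateGeometryError(
                f"0 < r_ne < r_edge violated at theta = {ang:.2f} deg")


@dataclass
class NormalizedPolarMap:
    """Fluorescence on the fixed normalized radial axis u in [-25, 100].

    ``values[i, k]`` is mean intensity and ``weight[i, k]`` the total
    Cartesian area deposited in the (theta_i, u_k) bin, so that
    ``(weight * values).sum()`` equals the polar-map total inside the cell
    edge.  ``raw_radius[i, k]`` carries the intensity-weighted mean raw
    radius (pixels) of the samples in the bin, falling back to the inverse
    of the u mapping where a bin received no mass.
    """

    values: np.ndarray          # (n_theta, n_u)
    weight: np.ndarray          # (n_theta, n_u)
    raw_radius: np.ndarray      # pixels, (n_theta, n_u)
    u: np.ndarray               # percent, (n_u,)
    theta: np.ndarray           # radians, (n_theta,)
    u_step: float
    center: tuple[float, float]
    pixel_size: float

    def weighted_total(self) -> float:
        return float((self.weight * self.values).sum())


def _ray_coordinates(center: tuple[float, float], theta: np.ndarray,
                     radii: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows = center[0] + np.outer(np.sin(theta), radii)
    cols = center[1] + np.outer(np.cos(theta), radii)
    return rows, cols


def _theta_grid(theta_step_deg: float) -> np.ndarray:
    n = 360.0 / theta_step_deg
    if abs(n - round(n)) > 1e-9:
        raise UsageError(f"theta_step {theta_step_deg} does not divide 360 evenly")
    return np.deg2rad(np.arange(round(n)) * theta_step_deg)


def sweep_polar(image: ImagePlane, center: tuple[float, float],
                theta_step: float = 0.1, radial_step: float = 0.5,
                cell_mask: np.ndarray | None = None,
                r_max: float | None = None) -> PolarMap:
    """Resample an image onto an (angle, radius) grid about ``center``.

    The maximal radius reaches ``R_MAX_MARGIN_PX`` beyond the furthest
    cell-mask pixel from the center (or the furthest image corner when no
    mask is given).  Samples falling outside the image evaluate to 0.
    """
    h, w = image.shape
    if not (0 <= center[0] <= h - 1 and 0 <= center[1] <= w - 1):
        raise UsageError(f"center {center} outside image of shape {image.shape}")
    if r_max is None:
        if cell_mask is not None and cell_mask.any():
            rows, cols = np.nonzero(cell_mask)
            d = np.hypot(rows - center[0], cols - center[1])
            r_max = float(d.max()) + R_MAX_MARGIN_PX
        else:
            corners = np.array([[0, 0], [0, w - 1], [h - 1, 0], [h - 1, w - 1]], float)
            r_max = float(np.hypot(*(corners - np.asarray(center)).T).max())
    theta = _theta_grid(theta_step)
    radii = np.arange(0.0, r_max + radial_step, radial_step)
    rows, cols = _ray_coordinates(center, theta, radii)
    values = map_coordinates(image.pixels, [rows, cols], order=1,
                             mode="constant", cval=0.0)
    return PolarMap(values=values, theta=theta, radii=radii,
                    theta_step_deg=theta_step, radial_step_px=radial_step,
                    r_max=r_max, center=(float(center[0]), float(center[1])),
                    pixel_size=image.pixel_size)


def _last_crossing(profile: np.ndarray, radii: np.ndarray,
                   label: str, theta: np.ndarray) -> np.ndarray:
    """Radius of the last 0.5-crossing of an interpolated mask profile.

    Uses the LAST sample at or above 0.5 along each ray (robust to holes
    in the mask) and refines the crossing to subpixel precision by linear
    interpolation between the bracketing samples.
    """
    inside = profile >= 0.5
    has = inside.any(axis=1)
    if not has.all():
        ang = np.rad2deg(theta[np.nonzero(~has)[0][0]])
        raise DegenerateGeometryError(
            f"ray at theta = {ang:.2f} deg never crosses the {label} mask")
    n_r = profile.shape[1]
    last = n_r - 1 - np.argmax(inside[:, ::-1], axis=1)
    r = radii[last].astype(float)
    step = radii[1] - radii[0] if radii.size > 1 else 1.0
    nxt = np.minimum(last + 1, n_r - 1)
    v0 = np.take_along_axis(profile, last[:, None], axis=1)[:, 0]
    v1 = np.take_along_axis(profile, nxt[:, None], axis=1)[:, 0]
    denom = v0 - v1
    frac = np.where((nxt > last) & (denom > 1e-12),
                    np.clip((v0 - 0.5) / np.where(denom > 1e-12, denom, 1.0), 0, 1),
                    0.0)
    return r + frac * step


def boundary_radii(masks: CellMasks, center: tuple[float, float],
                   theta_step: float = 0.1, radial_step: float = 0.5,
                   smooth_window_deg: float = 0.0) -> BoundaryRadii:
    """Find, per angle, the radius of the nuclear envelope and of the cell
    edge along rays from ``center``.

    Both masks are sampled bilinearly along each ray; the boundary is the
    last 0.5-crossing, which assumes the masks are star-convex about the
    center (a hole in the mask does not truncate the boundary, but a ray
    that never meets a mask raises :class:`DegenerateGeometryError` naming
    the angle).  ``smooth_window_deg`` > 0 applies a circular moving
    average to both radius profiles.
    """
    theta = _theta_grid(theta_step)
    h, w = masks.cell.shape
    rows, cols = np.nonzero(masks.cell)
    if rows.size == 0:
        raise DegenerateGeometryError("empty cell mask")
    r_max = float(np.hypot(rows - center[0], cols - center[1]).max()) + R_MAX_MARGIN_PX
    radii = np.arange(0.0, r_max + radial_step, radial_step)
    rr, cc = _ray_coordinates(center, theta, radii)
    prof_n = map_coordinates(masks.nucleus.astype(np.float64), [rr, cc],
                             order=1, mode="constant", cval=0.0)
    prof_c = map_coordinates(masks.cell.astype(np.float64), [rr, cc],
                             order=1, mode="constant", cval=0.0)
    r_ne = _last_crossing(prof_n, radii, "nucleus", theta)
    r_edge = _last_crossing(prof_c, radii, "cell", theta)
    if smooth_window_deg > 0:
        win = max(1, int(round(smooth_window_deg / theta_step)))
        kernel = np.ones(win) / win
        pad = win // 2 + 1
        for arr in (r_ne, r_edge):
            ext = np.concatenate([arr[-pad:], arr, arr[:pad]])
            sm = np.convolve(ext, kernel, mode="same")[pad:pad + arr.size]
            arr[:] = sm
    return BoundaryRadii(theta=theta, r_ne=r_ne, r_edge=r_edge)


def radius_to_u(r: np.ndarray, r_ne: np.ndarray, r_edge: np.ndarray) -> np.ndarray:
    """Piecewise mapping from raw radius to normalized coordinate u."""
    cyto = 100.0 * (r - r_ne) / (r_edge - r_ne)
    nuc = 25.0 * (r / r_ne - 1.0)
    return np.where(r >= r_ne, cyto, nuc)


def u_to_radius(u: np.ndarray, r_ne: np.ndarray, r_edge: np.ndarray) -> np.ndarray:
    """Inverse of :func:`radius_to_u`."""
    cyto = r_ne + (u / 100.0) * (r_edge - r_ne)
    nuc = r_ne * (1.0 + u / 25.0)
    return np.where(u >= 0.0, cyto, nuc)


def normalize_radial(pmap: PolarMap, radii: BoundaryRadii,
                     u_step: float = 0.5) -> NormalizedPolarMap:
    """Resample a polar map onto the fixed normalized radial axis.

    Per angle, each polar sample with radius r <= r_edge is mapped to u
    and its mass (area_weight * intensity) and area weight are split
    linearly between the two adjacent u-grid nodes (conservative
    carry-over); samples beyond the cell edge are dropped.  Total weighted
    intensity inside the cell edge is preserved exactly by construction.
    """
    if pmap.theta.shape != radii.theta.shape or not np.allclose(pmap.theta, radii.theta):
        raise UsageError("polar map and boundary radii use different theta grids")
    n_theta = pmap.theta.size
    u_grid = np.arange(U_MIN, U_MAX + 0.5 * u_step, u_step)
    n_u = u_grid.size

    r = pmap.radii[None, :]                        # (1, n_r)
    r_ne = radii.r_ne[:, None]
    r_edge = radii.r_edge[:, None]
    keep = np.broadcast_to(r, pmap.values.shape) <= r_edge

    u = radius_to_u(r, r_ne, r_edge)
    u = np.broadcast_to(u, pmap.values.shape)[keep]
    mass = (pmap.area_weight * pmap.values)[keep]
    wt = pmap.area_weight[keep]
    rad = np.broadcast_to(r, pmap.values.shape)[keep]
    ang_idx = np.broadcast_to(np.arange(n_theta)[:, None], pmap.values.shape)[keep]

    # linear (cloud-in-cell) deposition onto the u grid
    pos = np.clip((u - U_MIN) / u_step, 0.0, n_u - 1 - 1e-12)
    k0 = pos.astype(np.intp)
    frac = pos - k0
    flat0 = ang_idx * n_u + k0
    flat1 = ang_idx * n_u + np.minimum(k0 + 1, n_u - 1)

    dep_mass = np.zeros(n_theta * n_u)
    dep_wt = np.zeros(n_theta * n_u)
    dep_mr = np.zeros(n_theta * n_u)    # mass-weighted radius accumulator
    for flat, share in ((flat0, 1.0 - frac), (flat1, frac)):
        np.add.at(dep_mass, flat, mass * share)
        np.add.at(dep_wt, flat, wt * share)
        np.add.at(dep_mr, flat, mass * rad * share)

    dep_mass = dep_mass.reshape(n_theta, n_u)
    dep_wt = dep_wt.reshape(n_theta, n_u)
    dep_mr = dep_mr.reshape(n_theta, n_u)

    values = np.divide(dep_mass, dep_wt, out=np.zeros_like(dep_mass),
                       where=dep_wt > 0)
    r_geo = u_to_radius(u_grid[None, :], radii.r_ne[:, None], radii.r_edge[:, None])
    raw_radius = np.divide(dep_mr, dep_mass, out=r_geo.copy(), where=dep_mass > 0)
    return NormalizedPolarMap(values=values, weight=dep_wt, raw_radius=raw_radius,
                              u=u_grid, theta=pmap.theta.copy(), u_step=u_step,
                              center=pmap.center, pixel_size=pmap.pixel_size)
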