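"""Macular thickness maps: fovea localization, resampling, sector means.

Thickness maps arrive on the acquisition raster (A-scan spacing along x,
B-scan spacing along y, both in mm). The foveal pit is located as the
minimum of the map smoothed with a 0.05 mm circular kernel, the map is
resampled to a regular 0.02 mm grid with cubic interpolation, and mean
thickness is reported over the central 1 mm disc and the 1-2.5 mm annulus.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import RegularGridInterpolator

from .errors import InputError
from .types import SectorThickness, ThicknessMap

__all__ = ["locate_fovea", "resample_grid", "sector_means"]

SMOOTH_RADIUS_MM = 0.05
RESAMPLE_SPACING_MM = 0.02
FOVEA_RADIUS_MM = 0.5
PARAFOVEA_RADIUS_MM = 1.25


def _circular_kernel(radius_mm: float, sx: float, sy: float) -> np.ndarray:
    """Pixels whose center lies within radius of the kernel center."""
    rx = int(np.floor(radius_mm / sx))
    ry = int(np.floor(radius_mm / sy))
    xs = np.arange(-rx, rx + 1) * sx
    ys = np.arange(-ry, ry + 1) * sy
    k = (ys[:, None] ** 2 + xs[None, :] ** 2) <= radius_mm**2
    return k.astype(float) / k.sum()


def locate_fovea(retina: ThicknessMap) -> tuple[float, float]:
    """Foveal center (x, y) in mm: argmin of the smoothed total-retina map.

    Ties are broken by proximity to the map center; a flat map warns and
    returns the map center.
    """
    ext_x, ext_y = retina.extent_mm
    if ext_x < 3.0 or ext_y < 3.0:
        raise InputError("thickness map must cover at least 3 x 3 mm")
    k = _circular_kernel(SMOOTH_RADIUS_MM, retina.spacing_x_mm, retina.spacing_y_mm)
    smooth = ndi.convolve(retina.values, k, mode="nearest")
    h, w = smooth.shape
    cx_mm, cy_mm = (w - 1) / 2 * retina.spacing_x_mm, (h - 1) / 2 * retina.spacing_y_mm
    if np.ptp(smooth) == 0:
        warnings.warn("flat thickness map: returning the map center")
        return (cx_mm, cy_mm)
    mn = smooth.min()
    rr, cc = np.nonzero(smooth == mn)
    xs, ys = cc * retina.spacing_x_mm, rr * retina.spacing_y_mm
    i = int(np.argmin((xs - cx_mm) ** 2 + (ys - cy_mm) ** 2))
    return (float(xs[i]), float(ys[i]))


def resample_grid(m: ThicknessMap, spacing_mm: float = RESAMPLE_SPACING_MM) -> ThicknessMap:
    """Cubic resampling to an isotropic regular grid (no extrapolation)."""
    h, w = m.values.shape
    ext_x, ext_y = m.extent_mm
    if ext_x < spacing_mm or ext_y < spacing_mm:
        raise InputError("source map smaller than one output cell")
    if m.spacing_x_mm == spacing_mm and m.spacing_y_mm == spacing_mm:
        return ThicknessMap(m.layer, m.values.copy(), spacing_mm, spacing_mm)
    ys = np.arange(h) * m.spacing_y_mm
    xs = np.arange(w) * m.spacing_x_mm
    # cubic needs >= 4 samples per axis; fall back to linear on sparse axes
    method = "cubic" if min(h, w) >= 4 else "linear"
    interp = RegularGridInterpolator((ys, xs), m.values, method=method)
    ny = np.arange(0.0, ys[-1] + 1e-9, spacing_mm)
    nx = np.arange(0.0, xs[-1] + 1e-9, spacing_mm)
    gy, gx = np.meshgrid(ny, nx, indexing="ij")
    vals = interp(np.column_stack([gy.ravel(), gx.ravel()])).reshape(gy.shape)
    return ThicknessMap(m.layer, np.maximum(vals, 0.0), spacing_mm, spacing_mm)


def sector_means(m: ThicknessMap, center_mm: tuple[float, float]) -> SectorThickness:
    """Mean thickness over the foveal disc and parafoveal annulus.

    Sectors extending beyond the map trigger a partial-coverage warning and
    average the available points only.
    """
    h, w = m.values.shape
    cx, cy = center_mm
    ext_x, ext_y = m.extent_mm
    if not (0 <= cx <= ext_x and 0 <= cy <= ext_y):
        raise InputError(f"center {center_mm} outside map extent {(ext_x, ext_y)}")
    xs = np.arange(w) * m.spacing_x_mm
    ys = np.arange(h) * m.spacing_y_mm
    r2 = (ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2
    fovea = r2 <= FOVEA_RADIUS_MM**2
    annulus = (r2 > FOVEA_RADIUS_MM**2) & (r2 <= PARAFOVEA_RADIUS_MM**2)
    partial = (
        cx - PARAFOVEA_RADIUS_MM < 0
        or cy - PARAFOVEA_RADIUS_MM < 0
        or cx + PARAFOVEA_RADIUS_MM > ext_x
        or cy + PARAFOVEA_RADIUS_MM > ext_y
    )
    if partial:
        warnings.warn("parafoveal annulus extends beyond the map: partial coverage")
    if not fovea.any() or not annulus.any():
        raise InputError("sector contains no grid points")
    return SectorThickness(
        layer=m.layer,
        foveal_mean_um=float(m.values[fovea].mean()),
        parafoveal_mean_um=float(m.values[annulus].mean()),
        fovea_center_mm=(float(cx), float(cy)),
        partial_coverage=bool(partial),
    )
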