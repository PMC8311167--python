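"""Foveal avascular zone segmentation and the regional geometry built on it.

The FAZ is the capillary-free territory at the foveal center. It is
segmented from the deep-plexus angiogram: top-hat enhancement, Gaussian
smoothing, Canny edge detection of vessel walls, morphological closing to
weld the walls into a vascularized territory, hole filling and opening, and
finally the avascular connected component nearest the image center. Its
centroid anchors the 1 mm foveal disc and the 1-2.5 mm parafoveal annulus
on which every regional descriptor is evaluated.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, morphology

from .contour import polygonal_perimeter
from .errors import InputError, SegmentationFailure, UsageError
from .morpho import close_disk, open_disk
from .types import FazSegmentation, IsotropicAngiogram, RegionGeometry

__all__ = ["segment_faz", "faz_metrics", "build_regions"]

FOVEA_RADIUS_UM = 500.0
PARAFOVEA_RADIUS_UM = 1250.0

DEFAULT_GAUSS_SIGMA_UM = 5.0
DEFAULT_CANNY_LOW_Q = 0.70
DEFAULT_CANNY_HIGH_Q = 0.90
DEFAULT_CLOSE_RADIUS_UM = 12.0
DEFAULT_OPEN_RADIUS_UM = 30.0
DEFAULT_MAX_HOLE_AREA_PX = 20000  # holes below 0.02 mm^2 are vessel gaps, not a FAZ
SEARCH_RADIUS_UM = 500.0  # how far from center a FAZ seed may sit


def _fill_small_holes(mask: np.ndarray, max_area_px: int) -> np.ndarray:
    """Fill enclosed background pockets smaller than ``max_area_px``.

    A plain hole fill would swallow the FAZ itself, which is exactly an
    enclosed avascular pocket; only capillary-scale gaps are closed.
    """
    holes = ndi.binary_fill_holes(mask) & ~mask
    labels, n = ndi.label(holes)
    if n == 0:
        return mask
    sizes = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    small = np.flatnonzero(sizes < max_area_px) + 1
    return mask | np.isin(labels, small)


def segment_faz(
    dvc_img: IsotropicAngiogram,
    tophat_radius_um: float = 15.0,
    gauss_sigma_um: float = DEFAULT_GAUSS_SIGMA_UM,
    canny_low_q: float = DEFAULT_CANNY_LOW_Q,
    canny_high_q: float = DEFAULT_CANNY_HIGH_Q,
    close_radius_um: float = DEFAULT_CLOSE_RADIUS_UM,
    open_radius_um: float = DEFAULT_OPEN_RADIUS_UM,
    max_hole_area_px: int = DEFAULT_MAX_HOLE_AREA_PX,
    downsample: int = 1,
) -> FazSegmentation:
    """Segment the FAZ from a calibrated deep-plexus angiogram.

    With ``downsample`` > 1 the segmentation runs on a block-averaged copy
    of the image and the returned mask is upsampled back to 1 um/px; this
    trades a little boundary fidelity for speed and is off by default.

    Raises :class:`SegmentationFailure` when no avascular component lies
    within 0.5 mm of the image center (fully vascularized or off-center
    scan), or when the candidate is implausibly large (edge leak: the
    "avascular" region is just unenclosed background).
    """
    if dvc_img.meta.plexus != "DVC":
        raise UsageError("FAZ segmentation is defined on the DVC angiogram")
    h0, w0 = dvc_img.shape
    if min(h0, w0) < 1500:
        raise InputError("image must cover at least 1.5 mm for FAZ segmentation")

    ds = max(int(downsample), 1)
    px = dvc_img.pixels.astype(float)
    if ds > 1:
        hc, wc = (h0 // ds) * ds, (w0 // ds) * ds
        px = px[:hc, :wc].reshape(hc // ds, ds, wc // ds, ds).mean(axis=(1, 3))
    h, w = px.shape
    scale = 1.0 / ds  # um -> coarse px
    tophat_radius_um = tophat_radius_um * scale
    gauss_sigma_um = gauss_sigma_um * scale
    close_radius_um = close_radius_um * scale
    open_radius_um = open_radius_um * scale
    max_hole_area_px = int(max_hole_area_px * scale**2)
    search_px = SEARCH_RADIUS_UM * scale

    enhanced = morphology.white_tophat(
        np.clip(np.rint(px), 0, 255).astype(np.uint8),
        morphology.disk(max(int(round(tophat_radius_um)), 1), decomposition="sequence"),
    ).astype(float)
    edges = feature.canny(
        enhanced,
        sigma=gauss_sigma_um,
        low_threshold=canny_low_q,
        high_threshold=canny_high_q,
        use_quantiles=True,
    )
    vascular = close_disk(edges, close_radius_um)
    vascular = _fill_small_holes(vascular, max_hole_area_px)
    # opening the avascular complement severs the narrow inter-capillary
    # corridors that would otherwise connect the FAZ to the background
    avascular = open_disk(~vascular, open_radius_um)
    labels, _ = ndi.label(avascular, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    lab = labels[int(round(cy)), int(round(cx))]
    if lab == 0:
        # nearest avascular pixel within the search radius
        yy, xx = np.nonzero(avascular)
        if yy.size == 0:
            raise SegmentationFailure("no avascular region anywhere in the image")
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        best = int(np.argmin(d2))
        if d2[best] > search_px**2:
            raise SegmentationFailure(
                "no avascular component within 0.5 mm of the image center"
            )
        cand = np.unique(labels[yy[d2 <= search_px**2], xx[d2 <= search_px**2]])
        # ties (several components in range): keep the largest
        sizes = ndi.sum_labels(np.ones_like(labels), labels, cand)
        lab = int(cand[np.argmax(sizes)])

    mask = labels == lab
    if mask.sum() > 0.3 * mask.size:
        raise SegmentationFailure(
            "candidate avascular region spans the field; vasculature does not enclose a FAZ"
        )
    mask = ndi.binary_fill_holes(mask)
    if ds > 1:  # back to 1 um/px
        mask = np.repeat(np.repeat(mask, ds, axis=0), ds, axis=1)
        full = np.zeros((h0, w0), dtype=bool)
        full[: mask.shape[0], : mask.shape[1]] = mask[:h0, :w0]
        mask = full
    return faz_metrics(mask)


def faz_metrics(mask: np.ndarray) -> FazSegmentation:
    """Area/perimeter/circularity/centroid of a single-component FAZ mask.

    area = pixel count x 1e-6 mm^2 (1 um/px); perimeter from the polygonal
    contour estimator; circularity = 4*pi*area/perimeter^2 in consistent
    units (dimensionless, so the pixel scale cancels).
    """
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise InputError("empty FAZ mask")
    _, ncomp = ndi.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if ncomp != 1:
        raise InputError(f"FAZ mask must be a single 4-connected component, got {ncomp}")
    area_mm2 = n * 1e-6
    perim_px = polygonal_perimeter(mask)
    perimeter_mm = perim_px * 1e-3
    circularity = 4.0 * np.pi * area_mm2 / perimeter_mm**2
    yy, xx = np.nonzero(mask)
    centroid = (float(xx.mean()), float(yy.mean()))
    return FazSegmentation(
        mask=mask,
        area_mm2=area_mm2,
        perimeter_mm=perimeter_mm,
        circularity=float(circularity),
        centroid_um=centroid,
    )


def build_regions(center_um: tuple[float, float], shape: tuple[int, int]) -> RegionGeometry:
    """Foveal disc (r <= 500 um) and parafoveal annulus (500 < r <= 1250 um).

    Masks are clipped to the raster; ``clipped`` is set when the 2.5 mm disc
    does not fit entirely inside (partial parafovea, recorded not raised).
    """
    h, w = shape
    cx, cy = center_um
    if not (0 <= cx < w and 0 <= cy < h):
        raise InputError(f"center {center_um} lies outside the image {shape}")
    yy, xx = np.ogrid[:h, :w]
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    fovea = r2 <= FOVEA_RADIUS_UM**2
    parafovea = (r2 > FOVEA_RADIUS_UM**2) & (r2 <= PARAFOVEA_RADIUS_UM**2)
    clipped = (
        cx - PARAFOVEA_RADIUS_UM < 0
        or cy - PARAFOVEA_RADIUS_UM < 0
        or cx + PARAFOVEA_RADIUS_UM > w - 1
        or cy + PARAFOVEA_RADIUS_UM > h - 1
    )
    return RegionGeometry(
        center_um=(float(cx), float(cy)),
        fovea_mask=fovea,
        parafovea_mask=parafovea,
        clipped=bool(clipped),
    )
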