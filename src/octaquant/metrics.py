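"""Regional microvascular morphometrics from binary vessel maps.

Eight descriptors per (region x plexus), all on 1 um/px rasters:

* perfusion density — vessel-pixel fraction of the region (dimensionless);
* skeleton density — centerline length per region area (1/mm);
* vessel perimeter index — vessel boundary length per region area (1/mm);
* mean vessel diameter — vessel area / centerline length (um), which makes
  ``diameter x skeleton_density == 1000 x perfusion_density`` an exact
  algebraic identity;
* box-counting (Hausdorff) fractal dimension — slope of log N(eps) against
  log(1/eps) over a dyadic ladder of box sizes;
* gliding-box lacunarity — second moment over squared first moment of the
  vessel mass seen by a unit-stride sliding box; 1 for perfectly even
  cover, larger the gappier the pattern.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import morphology

from .contour import contour_chords
from .errors import InputError, ParameterError, UndefinedMetricError
from .types import (
    BinaryVesselMap,
    MicrovascularProfile,
    PerimeterMap,
    RegionGeometry,
    SkeletonMap,
)

__all__ = [
    "skeletonize_vessels",
    "vessel_perimeter",
    "perfusion_density",
    "skeleton_density",
    "vessel_perimeter_index",
    "mean_vessel_diameter",
    "fractal_dimension_boxcount",
    "lacunarity_glidingbox",
    "compute_profile",
]

DEFAULT_BOX_LADDER = (4, 8, 16, 32, 64, 128, 256, 512)
DEFAULT_LACUNARITY_BOX_PX = 512


def _check_region(region: np.ndarray, shape) -> np.ndarray:
    region = np.asarray(region).astype(bool)
    if region.shape != shape:
        raise InputError(f"region shape {region.shape} != map shape {shape}")
    if not region.any():
        raise InputError("empty region of interest")
    return region


def skeletonize_vessels(v: BinaryVesselMap) -> SkeletonMap:
    """Topology-preserving thinning to unit-width centerlines."""
    return SkeletonMap(mask=morphology.skeletonize(v.mask), source=v)


def vessel_perimeter(v: BinaryVesselMap) -> PerimeterMap:
    """Vessel boundary pixels: foreground 8-adjacent to background."""
    er = morphology.erosion(v.mask, np.ones((3, 3), dtype=bool))
    return PerimeterMap(mask=v.mask & ~er, source=v)


def perfusion_density(v: BinaryVesselMap, region: np.ndarray) -> float:
    """Vessel-pixel fraction of the region, in [0, 1]."""
    region = _check_region(region, v.shape)
    return float((v.mask & region).sum() / region.sum())


def skeleton_density(s: SkeletonMap, region: np.ndarray) -> float:
    """Centerline length per region area, 1/mm (1 skeleton px = 1e-3 mm)."""
    region = _check_region(region, s.mask.shape)
    length_mm = (s.mask & region).sum() * 1e-3
    area_mm2 = region.sum() * 1e-6
    return float(length_mm / area_mm2)


def vessel_perimeter_index(p: PerimeterMap, region: np.ndarray) -> float:
    """Vessel boundary length inside the region per region area, 1/mm.

    Boundary length uses the polygonal contour of the *source* vessel mask;
    chords whose midpoint falls in the region are counted, so the artificial
    rim that clipping a vessel map to a disc would create never enters.
    """
    region = _check_region(region, p.mask.shape)
    lengths, mids = contour_chords(p.source.mask)
    if lengths.size == 0:
        return 0.0
    rr = np.clip(np.rint(mids[:, 0]).astype(int), 0, region.shape[0] - 1)
    cc = np.clip(np.rint(mids[:, 1]).astype(int), 0, region.shape[1] - 1)
    length_mm = lengths[region[rr, cc]].sum() * 1e-3
    area_mm2 = region.sum() * 1e-6
    return float(length_mm / area_mm2)


def mean_vessel_diameter(v: BinaryVesselMap, s: SkeletonMap, region: np.ndarray) -> float:
    """Vessel area / centerline length inside the region, in um.

    Equivalent to ``1000 * perfusion_density / skeleton_density``; for a
    ribbon of width w this recovers w up to end effects.
    """
    region = _check_region(region, v.shape)
    skel_px = (s.mask & region).sum()
    if skel_px == 0:
        raise UndefinedMetricError("empty skeleton in region: diameter undefined")
    vessel_px = (v.mask & region).sum()
    return float(vessel_px / skel_px)  # um^2 per um at 1 um/px


def _box_counts(mask: np.ndarray, size: int) -> int:
    h, w = mask.shape
    nh, nw = -(-h // size), -(-w // size)
    padded = np.zeros((nh * size, nw * size), dtype=bool)
    padded[:h, :w] = mask
    return int(padded.reshape(nh, size, nw, size).any(axis=(1, 3)).sum())


def fractal_dimension_boxcount(
    v: BinaryVesselMap,
    region: np.ndarray,
    box_sizes: tuple[int, ...] = DEFAULT_BOX_LADDER,
) -> float:
    """Box-counting fractal dimension of vessel-in-region, clamped to [0, 2].

    Boxes tile the region's bounding box; a box counts when it contains at
    least one vessel pixel inside the region. The slope is an ordinary
    least-squares fit of log N against log(1/eps); scales with fewer than
    4 occupied boxes are dropped from the top of the ladder for stability.
    An empty mask yields 0 with a warning rather than an error.
    """
    region = _check_region(region, v.shape)
    inter = v.mask & region
    if not inter.any():
        warnings.warn("no vessel pixels in region: fractal dimension reported as 0")
        return 0.0
    rows = np.nonzero(inter.any(axis=1))[0]
    cols = np.nonzero(inter.any(axis=0))[0]
    sub = inter[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    limit = max(sub.shape)  # a thin bbox is still tileable along its long side
    sizes = [s for s in sorted(box_sizes) if s <= limit]
    if len(sizes) < 2:
        raise ParameterError("bounding box too small for the box ladder")
    counts = np.array([_box_counts(sub, s) for s in sizes])
    keep = np.ones(len(sizes), dtype=bool)
    for i in range(len(sizes) - 1, max(len(sizes) - 3, 0), -1):
        if counts[i] < 4:
            keep[i] = False
    if keep.sum() < 2:
        keep[:] = True
    x = np.log(1.0 / np.array(sizes, dtype=float)[keep])
    y = np.log(counts[keep].astype(float))
    slope = float(np.polyfit(x, y, 1)[0])
    return float(np.clip(slope, 0.0, 2.0))


def lacunarity_glidingbox(
    v: BinaryVesselMap, region: np.ndarray, box_size_px: int = DEFAULT_LACUNARITY_BOX_PX
) -> float:
    """Gliding-box lacunarity Lambda(r) = <M^2>/<M>^2 at unit stride.

    M is the vessel-in-region pixel mass of each box position (boxes lie
    fully inside the raster) whose center pixel falls inside the region.
    Lambda >= 1 always, with equality iff every counted box holds the same
    mass.
    """
    region = _check_region(region, v.shape)
    rows = np.nonzero(region.any(axis=1))[0]
    cols = np.nonzero(region.any(axis=0))[0]
    bb_h, bb_w = rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1
    b = int(box_size_px)
    if b < 1 or b > min(bb_h, bb_w):
        raise ParameterError(
            f"box size {b} exceeds the region bounding box {(bb_h, bb_w)}"
        )
    inter = (v.mask & region).astype(np.int64)
    # integral image -> mass of every b x b window at unit stride
    ii = np.zeros((inter.shape[0] + 1, inter.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(inter, axis=0), axis=1, out=ii[1:, 1:])
    m = ii[b:, b:] - ii[:-b, b:] - ii[b:, :-b] + ii[:-b, :-b]
    # keep windows whose center pixel is inside the region
    c = b // 2
    centers = region[c : c + m.shape[0], c : c + m.shape[1]]
    masses = m[centers].astype(float)
    if masses.size == 0:
        raise ParameterError("no box position has its center inside the region")
    mean = masses.mean()
    if mean == 0:
        raise UndefinedMetricError("all box masses are zero: lacunarity undefined")
    return float((masses**2).mean() / mean**2)


def _largest_pow2_leq(n: int) -> int:
    p = 1
    while p * 2 <= n:
        p *= 2
    return p


def compute_profile(
    svc_micro: BinaryVesselMap,
    dvc: BinaryVesselMap,
    regions: RegionGeometry,
    box_sizes: tuple[int, ...] = DEFAULT_BOX_LADDER,
    lacunarity_box_px: int = DEFAULT_LACUNARITY_BOX_PX,
) -> list[MicrovascularProfile]:
    """All eight descriptors for each (region x plexus): 4 profile rows.

    SVC capillary metrics use the microvessels-only map. When a region's
    bounding box cannot hold the requested lacunarity box, the box shrinks
    to the largest power of two that fits and the row is flagged.
    """
    if not svc_micro.microvessels_only:
        raise InputError("SVC map must be microvessels-only for capillary metrics")
    if svc_micro.shape != dvc.shape or svc_micro.shape != regions.fovea_mask.shape:
        raise InputError("vessel maps and regions must share a shape")
    out: list[MicrovascularProfile] = []
    for plexus, vmap in (("SVC", svc_micro), ("DVC", dvc)):
        skel = skeletonize_vessels(vmap)
        perim = vessel_perimeter(vmap)
        for region_name, region in (
            ("fovea", regions.fovea_mask),
            ("parafovea", regions.parafovea_mask),
        ):
            flags: list[str] = []
            pd = perfusion_density(vmap, region)
            sd = skeleton_density(skel, region)
            vpi = vessel_perimeter_index(perim, region)
            try:
                dia = mean_vessel_diameter(vmap, skel, region)
            except UndefinedMetricError:
                dia = None
                flags.append("diameter_undefined_empty_skeleton")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fd = fractal_dimension_boxcount(vmap, region, box_sizes)
            if not (vmap.mask & region).any():
                flags.append("fd_zero_empty_mask")
            rows = np.nonzero(region.any(axis=1))[0]
            cols = np.nonzero(region.any(axis=0))[0]
            bb = min(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
            box = lacunarity_box_px
            if box > bb:
                box = _largest_pow2_leq(bb)
                flags.append(f"lacunarity_box_reduced_to_{box}")
            try:
                lac = lacunarity_glidingbox(vmap, region, box)
            except (UndefinedMetricError, ParameterError) as exc:
                lac = None
                flags.append(f"lacunarity_undefined: {exc}")
            out.append(
                MicrovascularProfile(
                    region=region_name,
                    plexus=plexus,
                    perfusion_density=pd,
                    skeleton_density=sd,
                    vessel_perimeter_index=vpi,
                    mean_vessel_diameter=dia,
                    fractal_dimension=fd,
                    lacunarity=lac,
                    box_size_px=box,
                    flags=flags,
                )
            )
    return out
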