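"""Core data containers for the OCT-A quantification pipeline.

Conventions used throughout the package:

* rasters are row-major numpy arrays indexed ``[row, col]``;
* point coordinates are ``(x, y)`` pairs with ``x`` along columns and
  ``y`` along rows, in micrometres unless a field name says otherwise;
* boxes are 0-based half-open ``(x0, y0, x1, y1)`` rectangles;
* calibrated ("isotropic") images have a pixel pitch of exactly
  1 um/px on both axes, so pixel counts convert to physical units by
  pure powers of ten.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import GeometryError, InputError

EYES = ("OD", "OS")
PLEXUSES = ("SVC", "DVC")
REGIONS = ("fovea", "parafovea")
LAYERS = ("Retina", "mRNFL", "GCIPL", "INL", "OPL-ONL", "ELM-IS/OS")

#: physical pitch of every calibrated raster, micrometres per pixel
ISO_PITCH_UM = 1.0


@dataclass
class AcquisitionMeta:
    """Acquisition sidecar: who/which eye/which plexus plus the device scaling.

    ``scale_x_um``/``scale_y_um`` are the micrometres represented by one raw
    pixel along each axis; ``crop_box`` is the half-open rectangle (raw pixel
    coordinates) that removes the peripheral fundus rim before rescaling.
    """

    subject_id: str
    eye: str
    plexus: str
    scale_x_um: float
    scale_y_um: float
    crop_box: Optional[tuple[int, int, int, int]] = None
    field_label: str = ""

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise InputError(f"eye must be one of {EYES}, got {self.eye!r}")
        if self.plexus not in PLEXUSES:
            raise InputError(f"plexus must be one of {PLEXUSES}, got {self.plexus!r}")
        if not (self.scale_x_um > 0 and self.scale_y_um > 0):
            raise InputError("scale_x_um and scale_y_um must be strictly positive")
        if self.crop_box is not None:
            x0, y0, x1, y1 = self.crop_box
            if not (0 <= x0 < x1 and 0 <= y0 < y1):
                raise GeometryError(f"degenerate crop_box {self.crop_box}")

    def replace(self, **kw) -> "AcquisitionMeta":
        d = self.__dict__.copy()
        d.update(kw)
        return AcquisitionMeta(**d)


def _check_raster(pixels: np.ndarray, name: str) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.size == 0:
        raise InputError(f"{name} must be a nonempty 2-D raster, got shape {pixels.shape}")
    return pixels


@dataclass
class EnFaceAngiogram:
    """Raw (device-pitch) en face angiogram with 8-bit intensities."""

    pixels: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.pixels = _check_raster(self.pixels, "EnFaceAngiogram.pixels")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > 255:
            raise InputError(f"intensities must lie in [0, 255], got [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class IsotropicAngiogram:
    """Angiogram resampled to 1 px = 1 um on both axes."""

    pixels: np.ndarray
    meta: AcquisitionMeta
    pixel_pitch_um: float = ISO_PITCH_UM

    def __post_init__(self) -> None:
        self.pixels = _check_raster(self.pixels, "IsotropicAngiogram.pixels")
        if self.pixel_pitch_um != ISO_PITCH_UM:
            raise InputError("IsotropicAngiogram pitch must be exactly 1 um/px")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryVesselMap:
    """Binary vessel raster at 1 um/px.

    ``microvessels_only`` marks an SVC map after large-vessel subtraction;
    ``large_vessels`` marks the Otsu + caliber-floor large-vessel mask itself.
    """

    mask: np.ndarray
    plexus: str
    meta: AcquisitionMeta
    microvessels_only: bool = False
    large_vessels: bool = False

    def __post_init__(self) -> None:
        self.mask = _check_raster(self.mask, "BinaryVesselMap.mask").astype(bool)
        if self.plexus not in PLEXUSES:
            raise InputError(f"plexus must be one of {PLEXUSES}")
        if self.microvessels_only and self.plexus != "SVC":
            raise InputError("microvessels_only maps exist only for the SVC")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class SkeletonMap:
    """Unit-width centerline raster derived from a BinaryVesselMap."""

    mask: np.ndarray
    source: BinaryVesselMap

    def __post_init__(self) -> None:
        self.mask = _check_raster(self.mask, "SkeletonMap.mask").astype(bool)
        if self.mask.shape != self.source.shape:
            raise GeometryError("skeleton and source shapes differ")


@dataclass
class PerimeterMap:
    """Vessel boundary pixels (8-adjacent to both foreground and background)."""

    mask: np.ndarray
    source: BinaryVesselMap

    def __post_init__(self) -> None:
        self.mask = _check_raster(self.mask, "PerimeterMap.mask").astype(bool)
        if self.mask.shape != self.source.shape:
            raise GeometryError("perimeter and source shapes differ")


@dataclass
class FazSegmentation:
    """Foveal avascular zone mask plus its scalar geometry.

    area is the foreground pixel count times 1e-6 mm^2; circularity is
    4*pi*area/perimeter^2 (1 for a perfect disc, smaller for rougher or more
    elongated shapes); centroid is the foreground mean position in um.
    """

    mask: np.ndarray
    area_mm2: float
    perimeter_mm: float
    circularity: float
    centroid_um: tuple[float, float]

    def __post_init__(self) -> None:
        self.mask = _check_raster(self.mask, "FazSegmentation.mask").astype(bool)
        if self.circularity <= 0:
            raise InputError("circularity must be positive")


@dataclass
class RegionGeometry:
    """Foveal disc (1 mm diameter) and parafoveal annulus (1-2.5 mm).

    Both are centered on the same point (by protocol, the DVC FAZ centroid)
    and clipped to the image; ``clipped`` records whether the 2.5 mm disc
    extended beyond the raster.
    """

    center_um: tuple[float, float]
    fovea_mask: np.ndarray
    parafovea_mask: np.ndarray
    clipped: bool = False

    def __post_init__(self) -> None:
        self.fovea_mask = _check_raster(self.fovea_mask, "fovea_mask").astype(bool)
        self.parafovea_mask = _check_raster(self.parafovea_mask, "parafovea_mask").astype(bool)
        if self.fovea_mask.shape != self.parafovea_mask.shape:
            raise GeometryError("region masks must share a shape")
        if np.any(self.fovea_mask & self.parafovea_mask):
            raise GeometryError("fovea and parafovea masks overlap")


@dataclass
class MicrovascularProfile:
    """The eight regional microvascular descriptors for one (region, plexus).

    Units: perfusion_density dimensionless in [0, 1]; skeleton_density and
    vessel_perimeter_index in 1/mm; mean_vessel_diameter in um; fractal
    dimension dimensionless in [0, 2]; lacunarity dimensionless >= 1.
    """

    region: str
    plexus: str
    perfusion_density: float
    skeleton_density: float
    vessel_perimeter_index: float
    mean_vessel_diameter: Optional[float]
    fractal_dimension: float
    lacunarity: Optional[float]
    box_size_px: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise InputError(f"region must be one of {REGIONS}")
        if self.plexus not in PLEXUSES:
            raise InputError(f"plexus must be one of {PLEXUSES}")


@dataclass
class ThicknessMap:
    """Gridded per-layer thickness (um) with A-scan/B-scan spacings in mm."""

    layer: str
    values: np.ndarray
    spacing_x_mm: float
    spacing_y_mm: float

    def __post_init__(self) -> None:
        self.values = _check_raster(np.asarray(self.values, dtype=float), "ThicknessMap.values")
        if self.layer not in LAYERS:
            raise InputError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if not (self.spacing_x_mm > 0 and self.spacing_y_mm > 0):
            raise InputError("spacings must be positive")
        if np.any(self.values < 0):
            raise InputError("thickness values must be nonnegative")

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width, height) of the sampled area in mm."""
        h, w = self.values.shape
        return ((w - 1) * self.spacing_x_mm, (h - 1) * self.spacing_y_mm)


@dataclass
class SectorThickness:
    """Mean thickness (um) over the foveal disc and parafoveal annulus."""

    layer: str
    foveal_mean_um: float
    parafoveal_mean_um: float
    fovea_center_mm: tuple[float, float]
    partial_coverage: bool = False
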