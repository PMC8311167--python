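"""Fast binary morphology with exact Euclidean disc structuring elements.

On megapixel rasters, iterated rank filters with a large disc are the
bottleneck; erosion/dilation by a disc of radius r are equivalent to
thresholding a Euclidean distance transform, which costs two linear passes
regardless of r and uses the exact disc rather than a decomposition.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = ["dilate_disk", "erode_disk", "open_disk", "close_disk"]


def dilate_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    """Binary dilation by a Euclidean disc of the given radius (pixels)."""
    if radius <= 0 or not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= radius


def erode_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    """Binary erosion by a Euclidean disc of the given radius (pixels)."""
    if radius <= 0 or not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(mask) > radius


def open_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    """Opening: removes structures narrower than ~2*radius."""
    return dilate_disk(erode_disk(mask, radius), radius)


def close_disk(mask: np.ndarray, radius: float) -> np.ndarray:
    """Closing: bridges gaps narrower than ~2*radius."""
    return erode_disk(dilate_disk(mask, radius), radius)
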