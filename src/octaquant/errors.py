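"""Exception hierarchy.

Every error raised by the package derives from :class:`OctaquantError` so
callers can catch pipeline failures without masking programming errors.
"""


class OctaquantError(Exception):
    """Base class for all package errors."""


class InputError(OctaquantError):
    """Unreadable, empty, or structurally invalid input."""


class GeometryError(OctaquantError):
    """Shape or coordinate mismatch between rasters/regions."""


class ParameterError(OctaquantError):
    """Configuration value outside its valid range for the given input."""


class UsageError(OctaquantError):
    """Operation applied to the wrong plexus or in the wrong order."""


class SegmentationFailure(OctaquantError):
    """No plausible foveal avascular zone found near the image center."""


class UndefinedMetricError(OctaquantError):
    """A morphometric descriptor is undefined for this input (e.g. empty skeleton)."""


class FitError(OctaquantError):
    """Statistical model failed to converge or the design is singular."""
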