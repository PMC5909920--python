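"""Exception types shared across the pipeline."""


class PlantspaceError(Exception):
    """Base class for all package errors."""


class InvalidCameraError(PlantspaceError):
    """Camera parameters violate their physical constraints."""


class OutOfFrameError(PlantspaceError):
    """Pixel coordinate lies outside the image bounds."""


class InvalidInputError(PlantspaceError):
    """An argument is malformed (wrong shape, negative length, ...)."""


class GeometryViolationError(PlantspaceError):
    """A configuration is geometrically impossible (e.g. plant taller than 2H)."""


class DegenerateHistogramError(PlantspaceError):
    """Otsu thresholding received a constant image."""


class NoRidgeError(PlantspaceError):
    """An operation requiring at least one ridge received none."""


class UndefinedMetricError(PlantspaceError):
    """An accuracy metric was requested on empty input."""


class PairingError(PlantspaceError):
    """Paired metric inputs have mismatched lengths."""


class EmptySceneError(PlantspaceError):
    """The simulated scene extent cannot hold a single plant."""


class ConfigError(PlantspaceError):
    """Run configuration is missing fields or fails validation."""
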