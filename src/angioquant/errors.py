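"""Exception hierarchy shared across the toolbox."""


class AngioquantError(Exception):
    """Base class for all toolbox errors."""


class ValidationError(AngioquantError, ValueError):
    """An argument violates a documented precondition."""


class DecodeError(AngioquantError, IOError):
    """An input image file could not be read or has an unsupported format."""


class DegenerateImageError(AngioquantError, ValueError):
    """The image content cannot support the requested operation
    (e.g. a constant image offered to a two-cluster threshold)."""


class ConsistencyError(AngioquantError, ValueError):
    """Two inputs that must agree (shapes, masks, calibrations) do not."""


class FazSegmentationError(AngioquantError, RuntimeError):
    """Automatic FAZ segmentation found no plausible candidate; the caller
    should fall back to a manual contour."""
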