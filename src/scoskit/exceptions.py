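"""Exception types shared across scoskit modules."""


class ScosError(Exception):
    """Base class for scoskit errors."""


class InvalidParameterError(ScosError, ValueError):
    """A parameter violates its documented precondition."""


class LayoutError(ScosError, ValueError):
    """Channel layout is inconsistent with itself or with the frame geometry."""


class CalibrationError(ScosError, ValueError):
    """Camera calibration inputs are insufficient or inconsistent."""


class DegenerateTraceError(ScosError, ValueError):
    """A trace cannot be min-max normalized (max == min or too few valid samples)."""


class SegmentationError(ScosError, ValueError):
    """A time segment is empty or inconsistent with the record."""


class SpectralError(ScosError, ValueError):
    """Spectral analysis cannot proceed (trace too short, no in-band power, ...)."""


class FormatError(ScosError, ValueError):
    """An on-disk artifact does not match its declared format or sidecar."""


class SaturationWarning(UserWarning):
    """More than the allowed fraction of synthesized pixels hit the bit-depth ceiling."""
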