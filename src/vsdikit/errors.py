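"""Exception types shared across the toolbox."""


class VSDIError(Exception):
    """Base class for all toolbox errors."""


class InvalidParameterError(VSDIError, ValueError):
    """A user-supplied parameter violates its contract."""


class GeometryError(VSDIError):
    """Polygon construction failed (missing intersection, self-intersection, ...)."""


class ZeroBaselineError(VSDIError, ZeroDivisionError):
    """A pixel's baseline fluorescence is zero, so dF/F is undefined there."""


class NoActivationError(VSDIError):
    """A signal has no usable derivative peak inside the search window."""
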