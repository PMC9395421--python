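"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`PhotocytError`, so callers (and the CLI) can distinguish scientific /
configuration failures from genuine bugs.
"""


class PhotocytError(Exception):
    """Base class for all errors raised by photocyt."""


class ProtocolError(PhotocytError, ValueError):
    """Illumination protocol is inconsistent with the requested operation."""


class IntegrationError(PhotocytError, RuntimeError):
    """The ODE integrator failed or produced a non-finite solution."""


class DampingError(PhotocytError, ValueError):
    """Step heights carry no damping information (ratio >= 1, or zero steps)."""


class IdentifiabilityError(PhotocytError, ValueError):
    """The data cannot constrain the requested kinetic parameters."""


class FitError(PhotocytError, RuntimeError):
    """A nonlinear fit failed to converge."""


class ConfigError(PhotocytError, ValueError):
    """A run configuration or trace metadata field is missing or invalid."""


class AlignmentError(PhotocytError, ValueError):
    """Traces cannot be combined because their grids or metadata differ."""
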