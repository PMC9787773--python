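"""Exception hierarchy shared across the pipeline stages."""


class AcmeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AcmeError):
    """A file is structurally unreadable (missing axes, bad layout)."""


class ValidationError(AcmeError):
    """Data violates an invariant (negative counts, shape mismatch, ...)."""


class EmptyBandError(AcmeError):
    """A requested m/z band or time window does not intersect the grid."""


class ConfigError(AcmeError):
    """A configuration value is out of its admissible range."""


class PlacementError(AcmeError):
    """The simulator could not place peaks without overlap."""
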