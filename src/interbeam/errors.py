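"""Exception types shared across the package."""


class InterbeamError(Exception):
    """Base class for package errors."""


class ConfigurationError(InterbeamError):
    """Invalid user-supplied configuration (bad band, unknown material...)."""


class CalibrationError(InterbeamError):
    """Spectrum calibration could not reach the requested median."""


class RangeError(InterbeamError):
    """A requested coordinate (depth, energy, offset) is outside the data."""


class TruncationError(InterbeamError):
    """A profile does not extend far enough for the requested composition."""


class UnsupportedConfigurationError(InterbeamError):
    """A geometry the simplified model deliberately does not cover."""
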