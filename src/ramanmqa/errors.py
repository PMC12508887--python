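"""Exception hierarchy.

``UsageError`` maps to CLI exit code 1, every other :class:`MqaError`
subclass to exit code 2 (data / processing failure).
"""


class MqaError(Exception):
    """Base class for all package errors."""


class UsageError(MqaError):
    """Bad invocation: unknown option, missing required configuration."""


class FormatError(MqaError):
    """Malformed input file (header, column names, non-finite values)."""


class AxisError(MqaError):
    """Wavenumber axis violates its invariants (non-monotone, too short)."""


class GridError(MqaError):
    """Pixel-grid shape mismatch between maps or cubes."""


class ConfigError(MqaError):
    """Parameter combination violates an operation's preconditions."""


class CalibrationError(MqaError):
    """Axis calibration could not locate the reference band."""


class SelectionError(MqaError):
    """Model / internal-standard selection has no valid candidate."""


class FitError(MqaError):
    """Regression input is degenerate (e.g. a single distinct abscissa)."""
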