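"""Exception hierarchy shared across the package."""


class StandshiftError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StandshiftError):
    """Invalid stimulation/simulation configuration (bad times, levels, groups)."""


class DataError(StandshiftError):
    """Invalid data passed to a computation (non-finite, empty, wrong shape)."""


class SpanError(StandshiftError):
    """A requested time range falls outside the data's span."""


class AlignmentError(StandshiftError):
    """Streams cannot be synchronized (no overlapping time span)."""


class FormatError(StandshiftError):
    """A session container on disk is malformed or incomplete."""


class FitError(StandshiftError):
    """A calibration fit is under-determined or degenerate."""


class GeometryError(StandshiftError):
    """Marker geometry is degenerate (e.g. zero height above the plate)."""
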