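"""Exception hierarchy.

Every error raised on bad scientific input derives from :class:`MsbdynError`
so callers can catch the package's own failures separately from programming
errors.
"""


class MsbdynError(Exception):
    """Base class for all package errors."""


class ConfigError(MsbdynError, ValueError):
    """Invalid scene or analysis configuration; message names the field."""


class CalibrationError(MsbdynError, ValueError):
    """Objects measured on grids with incompatible physical calibrations."""


class NoDendriteError(MsbdynError, ValueError):
    """No dendritic shaft could be detected in the fill channel."""


class InsufficientDataError(MsbdynError, ValueError):
    """Too few observations for the requested computation."""


class DegenerateVarianceError(MsbdynError, ValueError):
    """A variance-based statistic was requested on zero-variance samples."""


class DimensionMismatchError(MsbdynError, ValueError):
    """Coordinates with incompatible dimensionality (e.g. missing z)."""
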