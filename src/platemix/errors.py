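"""Exception hierarchy shared across the package."""


class PlatemixError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PlatemixError, ValueError):
    """An EMG component or mixture parameter violates its constraints."""


class InputError(PlatemixError, ValueError):
    """Input data violate a precondition (too few values, non-finite, ...)."""


class ConfigError(PlatemixError, ValueError):
    """A simulation or run configuration is invalid; names the offending field."""


class DegenerateFitError(PlatemixError, RuntimeError):
    """EM collapsed (vanishing weight or scale) even after a restart."""


class CalibrationError(PlatemixError, ValueError):
    """Bead table cannot support an unambiguous standard curve."""


class FormatError(PlatemixError, ValueError):
    """A file failed validation; message lists the offending rows."""
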