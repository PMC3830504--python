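"""Exception hierarchy for eogkit."""


class EOGError(Exception):
    """Base class for all eogkit errors."""


class InputError(EOGError, ValueError):
    """Invalid input data or arguments (bad lengths, non-finite samples, ...)."""


class CalibrationError(EOGError):
    """Automatic threshold estimation failed (e.g. too few signal peaks)."""


class ConfigError(EOGError, ValueError):
    """Invalid configuration value or combination."""


class NumericalError(EOGError):
    """A numerical procedure failed (e.g. rank-deficient polynomial fit)."""
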