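"""Exception hierarchy for endospec."""


class EndospecError(Exception):
    """Base class for all endospec errors."""


class ParameterError(EndospecError, ValueError):
    """An argument violates a documented precondition."""


class UnsupportedBandError(ParameterError):
    """Band centre wavelength outside the supported analysis range."""


class ConfigurationError(EndospecError):
    """A rig or run configuration is missing or inconsistent."""


class SequenceLoadError(EndospecError):
    """A multispectral sequence could not be loaded; message names the entry."""


class MeasurementError(EndospecError):
    """A point-to-point measurement referenced an invalid pixel."""
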