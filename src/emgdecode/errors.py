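"""Exception hierarchy shared across the package."""


class EmgDecodeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EmgDecodeError):
    """A spec/config object violates its invariants."""


class DataError(EmgDecodeError):
    """Input data violates a contract (length mismatch, non-finite, ...)."""


class ShapeError(EmgDecodeError):
    """An array does not have the required shape."""


class IOFormatError(EmgDecodeError):
    """A file could not be parsed into the expected recording layout."""


class TrainingError(EmgDecodeError):
    """Optimization diverged or produced non-finite parameters."""


class DegenerateDataError(EmgDecodeError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
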