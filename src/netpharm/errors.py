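"""Exception hierarchy shared across the pipeline."""


class NetpharmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NetpharmError, ValueError):
    """Raised when an input violates a documented precondition."""


class UndefinedRatioError(NetpharmError, ZeroDivisionError):
    """Raised when a rate or fraction has an empty or zero denominator."""


class FormatError(NetpharmError, ValueError):
    """Raised when a file does not match its declared tabular contract."""
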