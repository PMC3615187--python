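"""Exception hierarchy shared across the package."""


class TetralinkError(Exception):
    """Base class for all tetralink errors."""


class FormatError(TetralinkError):
    """An input file does not have the expected layout."""


class ValidationError(TetralinkError):
    """Parsed data violates a domain invariant."""


class ConfigurationError(TetralinkError):
    """A user-supplied option or parameter is unusable."""


class AlignmentError(TetralinkError):
    """Two labelled objects cannot be brought into register."""


class UndefinedRatioError(TetralinkError):
    """A ratio was requested with a zero denominator."""


class InsufficientDataError(TetralinkError):
    """Too few observations for the requested model fit."""
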