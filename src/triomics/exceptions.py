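"""Exception hierarchy.

Validation failures (bad parameters, malformed inputs) raise
:class:`ValidationError` subclasses so the CLI can map them to exit code 2;
anything else is a runtime failure (exit code 1).
"""


class TriomicsError(Exception):
    """Base class for all package errors."""


class ValidationError(TriomicsError, ValueError):
    """Invalid parameter or input value; names the offending field."""


class AlignmentError(ValidationError):
    """Sample identifiers do not line up across data sources."""


class DegenerateInputError(ValidationError):
    """Constant or rank-deficient input where variation is required."""


class InsufficientDataError(ValidationError):
    """Fewer observations than model parameters."""


class IdLookupError(TriomicsError, KeyError):
    """Requested identifier(s) absent from a table; lists offenders."""

    def __init__(self, kind: str, missing):
        self.kind = kind
        self.missing = list(missing)
        super().__init__(f"unknown {kind} id(s): {', '.join(map(str, self.missing))}")
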