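"""Exception hierarchy for ahnet.

All package errors derive from :class:`AHNError` so callers (and the CLI)
can distinguish domain failures from programming errors.
"""


class AHNError(Exception):
    """Base class for all ahnet errors."""


class InvalidInputError(AHNError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDomainError(AHNError, ValueError):
    """The input axis has zero width (zMin >= zMax)."""


class InsufficientDataError(AHNError, ValueError):
    """Too few samples for the requested operation."""


class EmptyIntervalError(InsufficientDataError):
    """A molecule interval contains no samples."""


class UnknownLabelError(AHNError, KeyError):
    """A label is not present in the label map."""


class MissingValuesError(AHNError, ValueError):
    """The feature matrix contains missing cells; impute first."""


class UnimputableColumnError(AHNError, ValueError):
    """A column has no observed value to compute an imputation mean from."""


class MalformedLineError(AHNError, ValueError):
    """A raw sensor file line does not have the expected token count."""

    def __init__(self, path, line_number, n_tokens, expected):
        self.path = path
        self.line_number = line_number
        self.n_tokens = n_tokens
        self.expected = expected
        super().__init__(
            f"{path}:{line_number}: expected {expected} tokens, found {n_tokens}"
        )


class SchemaVersionError(AHNError, ValueError):
    """A persisted model document has an unsupported schema version."""
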