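"""Exception hierarchy for the ecgtf pipeline.

Exit-code mapping used by the CLI: ParameterError/FormatError -> 2,
DegenerateDataError/InsufficientDataError -> 3.
"""


class EcgTfError(Exception):
    """Base class for all ecgtf errors."""


class ParameterError(EcgTfError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(EcgTfError, ValueError):
    """An input file does not match the expected on-disk format."""


class InsufficientDataError(EcgTfError):
    """Not enough data to perform the operation (e.g. < 2 R peaks)."""


class DegenerateDataError(EcgTfError):
    """Data is structurally unusable (all beats rejected, constant output, ...)."""


class InstabilityError(EcgTfError):
    """A transfer-function simulation produced non-finite values."""

    def __init__(self, message: str, first_bad_sample: int | None = None):
        super().__init__(message)
        self.first_bad_sample = first_bad_sample


class AlignmentError(EcgTfError):
    """Two SAECGs could not be R-aligned with a usable overlap."""
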