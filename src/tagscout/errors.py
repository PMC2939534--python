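"""Exception hierarchy shared across the package.

Validation problems (bad input files, out-of-range parameters) map to CLI
exit code 2; an infeasible amplicon tiling maps to exit code 3; anything
else is a crash (exit 1).
"""


class TagscoutError(Exception):
    """Base class for all package errors."""


class ValidationError(TagscoutError):
    """Input or parameter failed a documented precondition."""


class FormatError(ValidationError):
    """A sequence file could not be parsed as its declared format."""


class TilingError(TagscoutError):
    """No amplicon tiling satisfying the constraints exists.

    Carries the uncovered sub-interval so callers can report it.
    """

    def __init__(self, message: str, uncovered: tuple[int, int] | None = None):
        super().__init__(message)
        self.uncovered = uncovered
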