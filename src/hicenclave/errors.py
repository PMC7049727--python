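"""Exception hierarchy for hicenclave."""


class HicenclaveError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HicenclaveError):
    """A line of an input file could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class FormatError(HicenclaveError):
    """Input violates the declared format (e.g. position not on the bin grid)."""


class DegenerateInputError(HicenclaveError):
    """Input is too small or empty for the requested operation."""


class ConvergenceError(HicenclaveError):
    """An iterative solver failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        if residual is not None:
            message = f"{message} (residual={residual:.3e})"
        super().__init__(message)


class PreconditionError(HicenclaveError):
    """A documented precondition of an operation was violated."""


class DegenerateSplitError(HicenclaveError):
    """All Fiedler coordinates coincide; no informative bisection exists."""


class InsulationUndefinedError(HicenclaveError):
    """Expansion metric undefined: the partition has zero internal weight."""


class UniverseMismatchError(HicenclaveError):
    """Two clusterings do not share the same loci universe."""

    def __init__(self, only_left, only_right):
        self.only_left = sorted(only_left)
        self.only_right = sorted(only_right)
        super().__init__(
            "clusterings cover different loci universes; "
            f"{len(self.only_left)} loci only in the first "
            f"(e.g. {self.only_left[:5]}), {len(self.only_right)} only in "
            f"the second (e.g. {self.only_right[:5]})"
        )


class MissingFieldError(HicenclaveError):
    """A required optional field (e.g. track intensity) is absent."""
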