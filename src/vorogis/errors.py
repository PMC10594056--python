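"""Exception hierarchy shared by all pipeline stages."""


class VorogisError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VorogisError):
    """Input table does not match the expected dialect (e.g. missing X/Y column)."""


class ParseError(VorogisError):
    """A value in an input table could not be parsed."""


class EmptyInputError(VorogisError):
    """An operation received an empty pattern or table."""


class TooFewPointsError(VorogisError):
    """Fewer points/features than the operation requires."""


class DegenerateInputError(VorogisError):
    """Collinear/duplicate/zero-variance input that leaves the statistic undefined."""


class DuplicateSiteError(DegenerateInputError):
    """Two sites closer than the duplicate tolerance."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(f"duplicate sites within tolerance: {self.pairs}")


class InfeasibleSpecError(VorogisError):
    """A synthetic pattern spec whose rejection rate exceeds the feasibility cap."""


class CoverageError(VorogisError):
    """A point falls outside the tessellation coverage."""


class RangeError(VorogisError):
    """A distance grid or band exceeds its valid range."""


class UndefinedStatisticError(DegenerateInputError):
    """Statistic undefined for the supplied values (constant field, all zeros...)."""


class ConvergenceError(VorogisError):
    """Iterative routine failed to reach its tolerance."""


class ComparabilityError(VorogisError):
    """Cross-group comparison attempted with mismatched analysis parameters."""


class ContractError(VorogisError):
    """An internal contract between stages was violated."""
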