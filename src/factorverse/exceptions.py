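"""Exception types shared across the package."""


class FactorverseError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(FactorverseError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateItemError(FactorverseError, ValueError):
    """An item is constant or has a single occupied category."""


class UndefinedThresholdError(DegenerateItemError):
    """A contingency-table margin has fewer than two occupied categories."""


class SingularMatrixError(FactorverseError, ValueError):
    """A correlation matrix is singular; positive-definite repair may help."""


class RankDeficiencyError(FactorverseError, ValueError):
    """A loading or design matrix does not have full column rank."""


class CollinearityError(RankDeficiencyError):
    """Perfect collinearity between regression predictors."""


class MissingItemError(FactorverseError, KeyError):
    """Items required by a dimension are absent from a response matrix."""

    def __init__(self, items):
        self.items = list(items)
        super().__init__(f"missing item columns: {self.items}")


class UndefinedFitIndexError(FactorverseError, ValueError):
    """A fit index is undefined for the given chi-square inputs (e.g. TLI)."""


class SchemaError(FactorverseError, ValueError):
    """A data file does not match the declared schema."""


class ParseError(FactorverseError, ValueError):
    """A data file contains values that cannot be parsed as declared."""
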