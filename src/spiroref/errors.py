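"""Exception hierarchy shared across the package."""


class SpirorefError(Exception):
    """Base class for all package errors."""


class RangeError(SpirorefError, ValueError):
    """An input is outside the validated range of the prediction equations."""


class CohortFormatError(SpirorefError, ValueError):
    """A cohort file is structurally unreadable (e.g. missing mandatory column)."""


class CohortValidationError(SpirorefError, ValueError):
    """One or more cohort rows failed validation.

    ``row_errors`` is a list of ``(row_index, field, message)`` triples using
    0-based data-row indices (the header is not counted).
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = [f"row {i}, field '{f}': {m}" for i, f, m in self.row_errors]
        super().__init__("cohort validation failed:\n  " + "\n  ".join(lines))


class ConfigurationError(SpirorefError, ValueError):
    """A coefficient table, lookup or run configuration is invalid."""


class SingularDesignError(SpirorefError, ValueError):
    """The regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class UndefinedStatisticWarning(UserWarning):
    """A statistic is undefined for the given input (degenerate marginals,
    zero variance); the function returns NaN instead of raising."""
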