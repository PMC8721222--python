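"""Exception hierarchy for wheatfusion.

All package-specific failures derive from :class:`WheatFusionError` so callers
can catch one base class at pipeline boundaries.
"""


class WheatFusionError(Exception):
    """Base class for all wheatfusion errors."""


class InvalidDesignError(WheatFusionError, ValueError):
    """A field design with non-positive counts or inconsistent structure."""


class ValidationError(WheatFusionError, ValueError):
    """Input table failed schema or range validation.

    Carries ``rows``: offending row indices (when applicable).
    """

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class UnknownIndexError(WheatFusionError, KeyError):
    """Requested vegetation index acronym is not in the registry."""


class UndefinedValueError(WheatFusionError, ArithmeticError):
    """An index or error formula is undefined for the given inputs.

    Carries ``name`` (the index/quantity) and ``context`` (inputs or plot ids).
    """

    def __init__(self, message, name=None, context=None):
        super().__init__(message)
        self.name = name
        self.context = context


class NormalizationError(WheatFusionError, ValueError):
    """A series cannot be normalized (zero mean, or a degenerate group)."""

    def __init__(self, message, series=None):
        super().__init__(message)
        self.series = series
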