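"""Exception hierarchy for the sdli pipeline.

Every stage raises a subclass of :class:`SDLIError` so callers (and the CLI)
can map failures onto the three broad classes: configuration problems, data
problems, and statistical degeneracies.
"""


class SDLIError(Exception):
    """Base class for all sdli-specific errors."""


class ConfigurationError(SDLIError):
    """Invalid configuration: bad mapping policy, empty drug list, bad params."""


class DataError(SDLIError):
    """Malformed or unreadable input data."""


class FormatError(DataError):
    """Input file does not have the required columns/structure."""


class RowParseError(DataError):
    """One or more rows failed to parse; carries the offending row numbers."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(f"{message} (rows: {', '.join(map(str, rows))})")
        self.rows = rows


class StatisticalError(SDLIError):
    """Statistical degeneracy: undefined ratio, insufficient data, ..."""


class UndefinedRatioError(StatisticalError):
    """Lethality ratio undefined because the seizure denominator is zero."""


class InsufficientDataError(StatisticalError):
    """Too few observations to fit the model."""


class DegenerateDesignError(StatisticalError):
    """Predictor has zero variance; slope not identifiable."""


class UndefinedStatisticError(StatisticalError):
    """A diagnostic statistic is undefined for the given residuals."""


class ParameterError(ConfigurationError):
    """Synthetic-market parameters are invalid or infeasible."""


class AlignmentError(DataError):
    """Year sets of two series that must match do not."""


class PipelineStageError(SDLIError):
    """Wraps a failure inside a named pipeline stage with a remediation hint."""

    def __init__(self, stage: str, cause: BaseException, hint: str = ""):
        msg = f"pipeline stage '{stage}' failed: {cause}"
        if hint:
            msg += f" — {hint}"
        super().__init__(msg)
        self.stage = stage
        self.cause = cause
        self.hint = hint
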