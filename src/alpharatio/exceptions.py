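"""Exception types shared across the package."""


class AlphaRatioError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(AlphaRatioError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(AlphaRatioError):
    """Not enough data to perform the requested computation."""


class UndefinedStatisticError(AlphaRatioError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class UndefinedValueError(AlphaRatioError):
    """A derived value is undefined (e.g. zero denominator in a ratio)."""


class PipelineError(AlphaRatioError):
    """A pipeline stage failed; the message names the stage."""
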