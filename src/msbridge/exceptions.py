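"""Exception hierarchy.

All package errors derive from :class:`MsBridgeError` so callers (and the
CLI) can map failure classes to exit codes: configuration/parameter errors,
data errors, and solver-convergence errors are distinguished.
"""


class MsBridgeError(Exception):
    """Base class for all errors raised by msbridge."""


class InvalidParameterError(MsBridgeError, ValueError):
    """A parameter is outside its documented domain (e.g. band edges beyond
    Nyquist, K >= number of maps)."""


class InsufficientDataError(MsBridgeError, ValueError):
    """The input carries too few samples/peaks/pairs for the requested
    operation."""


class DegenerateDistributionError(MsBridgeError, ValueError):
    """All samples were excluded, leaving no mass to form a distribution."""


class SchemaError(MsBridgeError, ValueError):
    """Channel sets or table columns do not match the expected schema."""


class MissingCellError(MsBridgeError, ValueError):
    """A required design cell (subject x condition) is absent."""


class UndefinedStatisticError(MsBridgeError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class SupportViolationError(MsBridgeError, ValueError):
    """KL divergence is infinite: the reference distribution has zero mass
    where the argument distribution does not."""


class InfeasibleMarginalsError(MsBridgeError, ValueError):
    """No transport plan supported on Q can satisfy the requested marginals.
    A pseudocount on Q usually restores feasibility."""


class ConvergenceError(MsBridgeError, RuntimeError):
    """An iterative solver did not reach tolerance within max_iter."""

    def __init__(self, message: str, marginal_error: float | None = None):
        super().__init__(message)
        self.marginal_error = marginal_error


class GenerationError(MsBridgeError, RuntimeError):
    """Synthetic-data rejection sampling exhausted its budget."""


class MissingArtifactError(MsBridgeError, FileNotFoundError):
    """A pipeline step requires an artifact a previous command produces."""
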