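"""Exception hierarchy.

All package-raised errors derive from :class:`WheatGPCError` so callers
(and the CLI) can distinguish user/data errors from genuine bugs.
"""


class WheatGPCError(Exception):
    """Base class for all errors raised by wheatgpc."""


class ParameterError(WheatGPCError):
    """Invalid generator or pipeline parameters."""


class CalibrationError(WheatGPCError):
    """Empirical-line calibration is infeasible or degenerate."""


class IndexComputationError(WheatGPCError):
    """A vegetation-index denominator vanished for a sample."""


class ModelFitError(WheatGPCError):
    """Regression fit is infeasible (rank, size, or variance problems)."""


class EvaluationError(WheatGPCError):
    """Scoring or splitting inputs are inconsistent."""


class GridError(WheatGPCError):
    """Grid shapes, masks or predictor layers are inconsistent."""
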