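"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`CoxenPipeError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class CoxenPipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigValidationError(CoxenPipeError, ValueError):
    """A configuration invariant was violated; the message names the field."""


class AlignmentError(CoxenPipeError, ValueError):
    """Sample or gene identifiers of two containers could not be aligned."""


class DegenerateInputError(CoxenPipeError, ValueError):
    """An input is degenerate for the requested statistic (e.g. zero variance)."""


class CollinearityError(CoxenPipeError, ValueError):
    """Design matrix is rank deficient (covariate collinear with factors)."""


class FitError(CoxenPipeError, RuntimeError):
    """Model fitting failed or preconditions for fitting were not met."""


class ScoringError(CoxenPipeError, RuntimeError):
    """A cohort could not be scored with a trained model."""


class PredictionError(CoxenPipeError, RuntimeError):
    """Combination prediction failed (e.g. a drug's percentile track missing)."""


class EvaluationError(CoxenPipeError, RuntimeError):
    """Outcome evaluation failed (e.g. a single-class response vector)."""


class ParseError(CoxenPipeError, ValueError):
    """A delimited-text input file could not be parsed."""
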