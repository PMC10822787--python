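"""Exception hierarchy.

All package errors derive from :class:`TwinaceError` so callers can catch one
base class; each also derives from the closest builtin so generic handling
(``except ValueError``) keeps working.
"""


class TwinaceError(Exception):
    """Base class for all twinace errors."""


class FormatError(TwinaceError, ValueError):
    """Malformed input file (bad column, unknown zygosity code, ...)."""


class DuplicateRecordError(FormatError):
    """Two records share the same (family_id, birth_order)."""


class ConsistencyError(FormatError):
    """Records contradict their family's zygosity group (sex, arity)."""


class ValidationError(TwinaceError, ValueError):
    """Invalid configuration; message lists the offending fields."""


class DegenerateDesignError(TwinaceError, ValueError):
    """Rank-deficient covariate design in residualization."""


class DegenerateDataError(TwinaceError, ValueError):
    """Data do not support the requested statistic (zero SD, all flagged...)."""


class DomainError(TwinaceError, ValueError):
    """Value outside a transform's domain; message names the index."""


class LikelihoodError(TwinaceError, FloatingPointError):
    """Non-positive-definite observed covariance submatrix."""


class ConvergenceError(TwinaceError, RuntimeError):
    """No optimization start converged."""


class IdentificationError(TwinaceError, ValueError):
    """Requested model is not identified (e.g. both cross-sex correlations free)."""


class NestingError(TwinaceError, ValueError):
    """Likelihood-ratio test requested for a non-nested model pair."""
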