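"""Exception hierarchy for refugia.

Every error raised by the package derives from :class:`RefugiaError`, so
callers can catch the whole family with one clause while tests pin the
specific failure mode.
"""


class RefugiaError(Exception):
    """Base class for all refugia errors."""


class InvalidConfigurationError(RefugiaError):
    """Synthesis or pipeline configuration violates a precondition."""


class MissingRoostError(RefugiaError):
    """A distance computation was requested with no roosts available."""


class UnknownFieldError(RefugiaError):
    """A field id was referenced that does not exist in the landscape."""


class IncompleteCriteriaError(RefugiaError):
    """A criteria table is missing a value required for ranking."""


class InvalidWidthError(RefugiaError):
    """Fractile width outside the open interval (0, 1)."""


class ProtocolInfeasibleError(RefugiaError):
    """A field is too small to contain the survey circles."""


class ModelIntegrityError(RefugiaError):
    """The deposition model produced a physically impossible value."""


class NumericDegeneracyError(RefugiaError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class UndefinedCorrelationError(RefugiaError):
    """Correlation requested on a constant vector."""


class InconsistentInputsError(RefugiaError):
    """Two inputs that must share ids or structure do not."""


class InfeasibleGeometryError(RefugiaError):
    """Area bookkeeping implies a negative area."""
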