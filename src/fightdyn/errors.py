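"""Exception hierarchy.

Every error raised by the toolbox derives from :class:`FightDynError` so callers
can catch domain failures without swallowing programming errors.
"""


class FightDynError(Exception):
    """Base class for all toolbox errors."""


class SchemaError(FightDynError):
    """An input table is missing a required column or has the wrong layout."""


class CadenceError(FightDynError):
    """Trace timestamps are not uniformly spaced at the logging cadence."""


class RangeError(FightDynError):
    """A value lies outside its physical bounds (e.g. ActVSum outside [0, 2])."""


class ValidationError(FightDynError):
    """A field failed a domain validity check (unknown species, bad temperature...)."""


class DuplicationError(FightDynError):
    """The same fish id appears more than once where ids must be unique."""


class DomainError(FightDynError):
    """A numeric argument is outside the mathematical domain of an operation."""


class IntegrityError(FightDynError):
    """A structural invariant of an artifact is violated (asymmetry, bad diagonal)."""


class ShapeError(FightDynError):
    """Sequence lengths or array shapes are inconsistent."""


class SizeError(FightDynError):
    """Too few observations for the requested operation."""


class ParameterError(FightDynError):
    """An operation parameter is out of its allowed range or unrecognized."""


class DegenerateColumnError(FightDynError):
    """A column is constant (zero variance) where variation is required."""


class PairingError(FightDynError):
    """Two processed series cannot be compared (variant/channel mismatch)."""


class CollinearityError(FightDynError):
    """A design matrix is rank deficient."""


class DegenerateGeometryError(FightDynError):
    """A dissimilarity matrix admits no positive-eigenvalue embedding."""


class FitError(FightDynError):
    """The posterior sampler failed."""


class ConvergenceWarning(UserWarning):
    """Attached (non-fatally) to a fit whose split-chain R-hat exceeds 1.05."""
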