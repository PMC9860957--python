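"""Exception hierarchy for solvachrom."""


class SolvachromError(Exception):
    """Base class for all package errors."""


class ValidationError(SolvachromError):
    """A record or parameter violates its physical invariants."""


class SchemaError(SolvachromError):
    """An input table lacks a mandatory column."""


class InsufficientDataError(SolvachromError):
    """Too few points for a regression or dispersion estimate."""


class DegenerateDesignError(SolvachromError):
    """Regressor has zero variance (all solvents give the same abscissa)."""


class UndefinedSensitivityError(SolvachromError):
    """Dipole configuration for which A is not defined (|mu_e| == |mu_g|)."""


class UndefinedRatioError(SolvachromError):
    """E/C requested with C == 0."""


class SingularityError(SolvachromError):
    """Evaluation at the A == 1 pole of the emission-prediction formula."""
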