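"""Exception hierarchy.

All package-specific errors derive from :class:`MRError` so callers can
catch one base class at pipeline level while still distinguishing hard
input problems (format, configuration) from statistical degeneracies
(empty instrument sets, collinear exposures, non-convergence).
"""


class MRError(Exception):
    """Base class for all errors raised by mrmediation."""


class FormatError(MRError):
    """Malformed or empty summary-statistics input."""


class EmptySetError(MRError):
    """No SNPs left after harmonisation/selection; downstream estimators must surface this."""


class UndefinedRatioError(MRError):
    """Wald ratio with a zero exposure beta."""


class InsufficientInstrumentsError(MRError):
    """Fewer SNPs than the estimator requires."""


class CollinearityError(MRError):
    """Exposure beta matrix is rank deficient (or all-equal Egger bx)."""


class UnderIdentifiedError(MRError):
    """Fewer retained SNPs than exposures + 1 in multivariable MR."""


class DegenerateWeightError(MRError):
    """Non-positive inverse-variance weight encountered in Q_A."""


class DegenerateInputError(MRError):
    """Degenerate input values (e.g. all identical, rank transform undefined)."""


class InsufficientDataError(MRError):
    """Too few shared null SNPs for the phenotypic correlation matrix."""


class ConvergenceError(MRError):
    """Numerical minimisation failed; carries diagnostic detail."""

    def __init__(self, message, detail=None):
        super().__init__(message)
        self.detail = detail


class ConfigurationError(MRError):
    """Invalid simulation or pipeline configuration."""


class IncompleteInputsError(MRError):
    """Mediation inputs missing a required estimate."""


class UndefinedProportionError(MRError):
    """Proportion mediated with a zero total effect."""
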