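"""Exception hierarchy for hsekit."""


class HsekitError(Exception):
    """Base class for all package errors."""


class PanelError(HsekitError):
    """Malformed panel data (unbalanced, non-finite, bad schema)."""


class LogDomainError(PanelError):
    """A value that must be strictly positive before log transform is not."""


class DegeneratePCAError(HsekitError):
    """Output-index PCA cannot be computed (constant column)."""


class UnknownUnitError(HsekitError):
    """Unit identifier not present in the region map or weights."""


class DomainError(HsekitError):
    """Parameter outside its mathematical domain."""


class FitError(HsekitError):
    """Frontier maximum-likelihood estimation failed to converge.

    Carries the best point found so callers can inspect it.
    """

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class InfeasibleDistanceError(HsekitError):
    """A DEA envelopment program is infeasible (possible for cross-period VRS)."""

    def __init__(self, message, dmu=None, period=None):
        super().__init__(message)
        self.dmu = dmu
        self.period = period


class WeightsError(HsekitError):
    """Invalid spatial weights (isolate under row standardisation, shape mismatch)."""


class StateClassificationError(HsekitError):
    """Quartile cut points are not strictly increasing."""
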