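"""Exception hierarchy for halokin.

Every error raised by the package derives from :class:`HalokinError`, so
callers can catch one type at pipeline boundaries while the fitting and
simulation layers stay specific about what went wrong.
"""


class HalokinError(Exception):
    """Base class for all halokin errors."""


class ValidationError(HalokinError, ValueError):
    """Invalid parameter, concentration, or grid supplied by the caller."""


class ConfigError(HalokinError, KeyError):
    """A configuration file or optical model is missing a required entry."""


class IntegrationError(HalokinError, RuntimeError):
    """The stiff ODE integrator failed; the message names the failing interval."""


class DegenerateRatesError(HalokinError, ValueError):
    """Closed-form chain requested with k1 == k2 (the two-exponential form is singular)."""


class FitError(HalokinError, RuntimeError):
    """A least-squares fit failed to converge or the data do not support the model.

    When a best attempt exists it is attached as ``best_attempt``.
    """

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class DegenerateTraceError(FitError):
    """Trace has no dynamic range (constant signal); exponential fitting is meaningless."""


class UnidentifiableKdError(FitError):
    """Saturation data carry no curvature: Kd cannot be identified.

    Raised when the kobs-vs-concentration points are consistent with a
    straight line through the origin, or when every concentration lies so far
    above (or below) the half-saturation point that the dissociation constant
    is unconstrained.
    """


class UndefinedBranchError(HalokinError, ValueError):
    """Branching fraction requested with both competing rates equal to zero."""


class UndefinedFractionError(HalokinError, ValueError):
    """Amplitude partition requested on a trace with no completed rise."""


class BudgetInconsistencyError(HalokinError, ValueError):
    """Coupling ratio exceeds the HOX-forming flux fraction; the budget cannot close."""
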