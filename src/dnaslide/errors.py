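"""Exception types raised across the package."""


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class UnreachableTargetError(RuntimeError):
    """The probability of ever reaching the target is numerically zero.

    Raised when the survival-conditioned first-passage statistics would be
    meaningless because essentially no walker survives the transit
    (reach probability below ~1e-12).
    """


class HorizonTooShortError(RuntimeError):
    """A time horizon does not cover the event of interest (e.g. T_1/2)."""


class SolverError(RuntimeError):
    """The stiff ODE integration failed; carries solver diagnostics."""


class RunawayTrajectoryError(RuntimeError):
    """A Monte Carlo trajectory exceeded the configured step guard."""


class NoIntersectionError(RuntimeError):
    """Two fitted power laws are parallel and never intersect."""
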