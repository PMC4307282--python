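"""Exception hierarchy for the conjugate-composition pipeline."""


class NanoconjError(ValueError):
    """Base class for all pipeline errors."""


class DomainError(NanoconjError):
    """An input is outside the physical domain of an operation."""


class InsufficientDataError(NanoconjError):
    """Too few points / measurements to perform the requested operation."""


class DegenerateFitError(NanoconjError):
    """A regression cannot be performed or yields a physically meaningless
    result (zero concentration variance, nonnegative Scatchard slope, ...)."""


class UnusableCurveError(NanoconjError):
    """A calibration curve cannot be inverted (slope <= 0)."""


class PairingError(NanoconjError):
    """Sample readings cannot be matched to calibration conditions."""


class SolverError(NanoconjError):
    """The equilibrium root-finder failed to bracket a solution."""
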