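"""Exception hierarchy shared across the package."""


class HscdivError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HscdivError):
    """An input file does not match the expected schema (missing columns,
    unknown categorical values, unparseable cells)."""


class ValidationError(HscdivError):
    """Well-formed input whose values violate a domain invariant; the message
    names the offending rows and column."""


class DomainError(HscdivError, ValueError):
    """An argument lies outside the mathematical domain of an operation
    (age before t0, off-grid threshold, ...)."""


class DegenerateSampleError(HscdivError):
    """A sample for which the requested estimator is undefined, e.g. all
    observations identical so the beta likelihood is unbounded."""


class OptimizationError(HscdivError):
    """Optimizer failed to converge within the allotted restarts; carries the
    best point found so far in ``best`` when available."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class IntegrationError(HscdivError):
    """ODE solver failure; the message reports the age at which it failed."""
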