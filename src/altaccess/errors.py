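"""Exception hierarchy shared across the package."""


class AltaccessError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AltaccessError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(AltaccessError, ValueError):
    """A file does not follow the expected on-disk format."""


class SelectionError(AltaccessError, ValueError):
    """An atom/residue selection matched nothing."""


class StabilityError(AltaccessError, RuntimeError):
    """The stochastic integrator produced a divergent step."""


class ConvergenceError(AltaccessError, RuntimeError):
    """An iterative solver exhausted its iteration budget."""


class UnidentifiableError(AltaccessError, ValueError):
    """Data carry no information about the parameter being fitted."""


class OverlapError(AltaccessError, RuntimeError):
    """Distributions do not overlap enough for the estimator to apply."""
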