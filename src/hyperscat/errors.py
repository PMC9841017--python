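"""Exception hierarchy for the numerical kernels."""


class HyperscatError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HyperscatError, ValueError):
    """An input lies outside the mathematical domain of the operation
    (e.g. a Pochhammer pole, a non-existing negative moment, z <= 3 for
    the polydisperse-sphere Porod constant)."""


class ConvergenceError(HyperscatError, ArithmeticError):
    """A series or quadrature failed to reach the requested tolerance."""


class PrecisionLossError(HyperscatError, ArithmeticError):
    """Catastrophic cancellation detected: intermediate terms exceeded the
    guard factor times the partial sum.  The caller must switch to the
    asymptotic regime."""


class ConfigError(HyperscatError, ValueError):
    """Invalid or unknown run-configuration input."""
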