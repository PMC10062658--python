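"""Exception types shared across the package."""


class PthPulseError(Exception):
    """Base class for all package-specific errors."""


class InfeasibilityError(PthPulseError, ValueError):
    """A requested design violates a hard constraint (e.g. pulse longer than period)."""


class ConvergenceError(PthPulseError, RuntimeError):
    """An iterative or fixed-point computation failed to converge."""


class ExactAdaptationError(PthPulseError, ValueError):
    """Activity coefficients cannot satisfy the exact-adaptation condition."""
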