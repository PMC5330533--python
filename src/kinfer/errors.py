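"""Exception hierarchy.

Every failure mode of the pipeline maps onto one of these classes so that
callers (and the CLI exit-code table) can distinguish format problems from
identification, classification and conversion failures.
"""


class KinferError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(KinferError, ValueError):
    """A kinetic or transfer-function parameter violates its domain."""


class InstabilityError(KinferError):
    """A system with non-decaying modes (pole with Re >= 0) was produced."""


class UnsupportedDynamicsError(KinferError):
    """Complex poles (oscillatory dynamics) or other out-of-scope systems."""


class IdentifiabilityError(KinferError):
    """The regression problem is rank deficient (e.g. zero input)."""


class SamplingError(KinferError, ValueError):
    """Non-uniform or too-coarse sampling of a trace."""


class OptimizationFailureError(KinferError):
    """No start of the constrained least-squares problem converged."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class AmbiguousClassificationError(KinferError):
    """Feedback and parallel costs are too close to commit to a label."""


class InfeasibleSchemeError(KinferError):
    """A transition rate came out non-positive: mis-classified configuration."""


class ConversionIntegrityError(KinferError):
    """Reconstructed G_kin does not match the input transfer function."""


class MalformedSchemeError(KinferError):
    """Scheme graph is structurally invalid (singular Laplace system)."""


class NoiseSpecError(KinferError, ValueError):
    """Invalid noise specification (non-positive variance, bad SNR target)."""


class FilterSpecError(KinferError, ValueError):
    """Invalid pre-filter specification (cutoff at or above Nyquist)."""


class FormatError(KinferError, ValueError):
    """Trace file does not parse into a valid sampled trace."""
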