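"""Exception hierarchy."""


class PRCInferError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PRCInferError, ValueError):
    """A configuration or model parameter is out of its valid range."""


class GridMismatchError(PRCInferError, ValueError):
    """Inputs that must share a time grid do not."""


class InsufficientEventsError(PRCInferError):
    """Fewer events were detected than the operation requires."""


class UnderdeterminedSystemError(PRCInferError):
    """The linear system has fewer usable rows than unknowns."""


class IterationDivergenceError(PRCInferError):
    """The iterative fit produced a pathological phase (psi_m <= 0) or
    non-finite coefficients."""


class IntegrationError(PRCInferError):
    """A trajectory left the finite domain or an event stepped backwards."""


class NotOscillatingError(PRCInferError):
    """No section crossing found: the model does not oscillate from the
    given state."""


class PerturbationTooStrongError(PRCInferError):
    """A test pulse knocked the trajectory off the oscillation."""


class SectionSearchError(PRCInferError):
    """Every grid point of a Poincare-section search was invalid."""
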