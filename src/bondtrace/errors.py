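"""Exception hierarchy shared across bondtrace modules."""


class BondtraceError(Exception):
    """Base class for all bondtrace errors."""


class ValidationError(BondtraceError, ValueError):
    """Input data violates a structural invariant (e.g. non-cagemate event)."""


class ConfigurationError(BondtraceError, ValueError):
    """A configuration value is out of its admissible range."""


class DomainError(BondtraceError, ValueError):
    """An operation was called outside its mathematical domain."""


class DegenerateDesignError(BondtraceError, ValueError):
    """The regression design is degenerate (e.g. zero predictor variance)."""


class InferenceError(BondtraceError, RuntimeError):
    """Inference could not be completed (e.g. all permuted fits degenerate)."""


class ConvergenceWarning(UserWarning):
    """A fit converged poorly (separation, non-convergence); result flagged."""
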