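"""Exception hierarchy shared across the package."""


class RNSTError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RNSTError):
    """An option, name or hyperparameter is invalid or unsupported."""


class ValidationError(RNSTError):
    """An input array violates a precondition (range, finiteness, shape)."""


class ShapeError(ValidationError):
    """Array shapes are incompatible or too small for the operation."""


class DependencyError(ConfigurationError):
    """A requested component needs an optional dependency that is absent."""


class DivergenceError(RNSTError):
    """Optimization produced a non-finite loss.

    Carries ``iteration`` (the inner-step index at which the loss became
    non-finite) and, where available, a partial ``trace``.
    """

    def __init__(self, message, iteration=None, trace=None):
        super().__init__(message)
        self.iteration = iteration
        self.trace = trace
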