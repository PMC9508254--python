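"""Exception types shared across the package."""


class ForestNetsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ForestNetsError, ValueError):
    """A model or estimator parameter is outside its valid range."""


class DataError(ForestNetsError, ValueError):
    """Input data violate a precondition (missing columns, non-positive radii, ...)."""


class ConvergenceError(ForestNetsError, RuntimeError):
    """An iterative simulation failed to reach a valid state within its budget."""
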