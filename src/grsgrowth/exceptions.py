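"""Exception hierarchy used across the package."""


class GrsGrowthError(Exception):
    """Base class for package errors."""


class ConfigurationError(GrsGrowthError, ValueError):
    """A configuration value is invalid or inconsistent."""


class InputError(GrsGrowthError, ValueError):
    """Input data violate a precondition (shape, nesting, codes, ...)."""


class ConvergenceError(GrsGrowthError, RuntimeError):
    """An iterative fit failed to converge within its budget."""
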