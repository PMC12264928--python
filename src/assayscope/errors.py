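"""Exception hierarchy used across the toolkit."""


class AssayScopeError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(AssayScopeError):
    """An input table does not expose a required column."""


class IntegrityError(AssayScopeError):
    """An input violates a structural invariant (e.g. duplicate ids)."""


class DomainError(AssayScopeError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class ParameterError(AssayScopeError, ValueError):
    """A configuration parameter is invalid for the given input."""


class FeaturizationError(AssayScopeError):
    """A molecule or protein could not be featurized."""


class ConfigError(AssayScopeError):
    """A generator or pipeline configuration is inconsistent."""
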