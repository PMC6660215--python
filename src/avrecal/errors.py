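"""Exception hierarchy shared across the package."""


class AvrecalError(Exception):
    """Base class for package errors."""


class InvalidParameterError(AvrecalError, ValueError):
    """A generator or analysis parameter is outside its valid range."""


class DataError(AvrecalError, ValueError):
    """Input data violate a structural precondition (schema, alignment, classes)."""


class ConfigError(AvrecalError, ValueError):
    """A pipeline configuration is malformed or inconsistent."""
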