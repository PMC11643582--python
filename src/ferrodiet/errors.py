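"""Exception hierarchy shared across the package."""


class FerrodietError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FerrodietError):
    """A configuration value is invalid; the message names the field."""


class TableValidationError(FerrodietError):
    """A tabular input violates the schema; the message names row and field."""


class UnknownFoodError(FerrodietError):
    """A diary references a food code absent from the composition table."""


class StructuralError(FerrodietError):
    """Input data violates a structural assumption (e.g. not two survey days)."""


class ScheduleError(FerrodietError):
    """The reference-intake schedule does not cover the requested sex/age."""
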