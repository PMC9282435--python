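"""Exception hierarchy.

Argument-level misuse (bad scalar arguments, violated preconditions) raises
plain :class:`ValueError`; these classes cover structured-input problems.
"""


class ObesimError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(ObesimError):
    """An input table or configuration file is invalid or inconsistent."""


class SchemaError(ConfigurationError):
    """A delimited-text input does not match its documented column schema."""


class CoverageError(ObesimError):
    """A required (sex, age, year) stratum is missing from an input table."""


class UnderDeterminedError(ObesimError):
    """Too few distinct survey years to identify the requested trend form."""
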