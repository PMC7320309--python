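"""Exception hierarchy shared across the pipeline.

Each class maps to a distinct CLI exit code so shell callers can tell a
malformed input file from a bad parameter or a failed estimation.
"""


class PortalSessionsError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(PortalSessionsError):
    """Input file does not conform to the expected column schema."""

    exit_code = 2


class ParameterError(PortalSessionsError):
    """A caller-supplied parameter is out of its valid range."""

    exit_code = 3


class EstimationError(PortalSessionsError):
    """A data-driven estimate cannot be computed from the given data."""

    exit_code = 4


class TaxonomyError(PortalSessionsError):
    """Action-taxonomy configuration is invalid (ambiguous or malformed)."""

    exit_code = 5


class ConfigError(PortalSessionsError):
    """Pipeline or simulation configuration is invalid."""

    exit_code = 6
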