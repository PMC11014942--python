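"""Exception hierarchy shared across the pipeline."""


class NitrokitError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(NitrokitError):
    """A delta value is non-finite or otherwise unusable."""


class InvalidUncertaintyError(NitrokitError):
    """A 1-sigma uncertainty is negative."""


class ConfigurationError(NitrokitError):
    """A parameter, config file or endmember set is inconsistent."""


class DegenerateEndmemberError(NitrokitError):
    """The two endmembers coincide in the mixing tracer."""


class NoDataError(NitrokitError):
    """An operation received an empty collection."""


class EmptyInventoryError(NitrokitError):
    """No annotation column maps to any process in the panel."""


class SchemaError(NitrokitError):
    """Tabular input does not match the expected columns / process set."""


class EmptyProfileError(NitrokitError):
    """A SIP profile carries zero total abundance."""


class InsufficientFractionsError(NitrokitError):
    """Fewer gradient fractions than a shift statistic requires."""


class PairingError(NitrokitError):
    """13C/12C profiles disagree in target gene or temperature."""


class ParseError(NitrokitError):
    """A delimited-text input could not be parsed; carries row context."""
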