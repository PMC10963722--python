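"""Exception hierarchy."""


class HubseekError(Exception):
    """Base class for all package errors."""


class ParseError(HubseekError):
    """A file could not be parsed; the message names the offending line."""


class StructuralError(HubseekError):
    """Files parsed individually but are mutually inconsistent (e.g. row counts)."""


class ConfigurationError(HubseekError):
    """A requested sample, population or baseline member is absent."""


class UndefinedValueError(HubseekError):
    """A statistic has an empty denominator (zero qualifying sites/blocks)."""


class DegenerateBaselineError(HubseekError):
    """Reference baselines coincide, making a mixture equation non-invertible."""
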