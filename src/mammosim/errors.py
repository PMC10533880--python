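"""Exception types raised by mammosim."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class DemographyParseError(ValidationError):
    """A demography file is malformed; the message names file and row."""


class ConfigError(ValidationError):
    """A run configuration is incomplete or inconsistent."""
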