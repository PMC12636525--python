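"""Exception types shared across the pipeline."""


class MetapanError(Exception):
    """Base class for all package errors."""


class ConfigError(MetapanError, ValueError):
    """An impossible or inconsistent configuration was requested."""


class InputError(MetapanError, ValueError):
    """Input data violate a precondition (missing records, bad identifiers)."""


class ParseError(MetapanError, ValueError):
    """A file could not be parsed into the expected tabular dialect."""
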