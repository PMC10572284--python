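"""Exception types shared across the pipeline."""


class AlloscError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AlloscError):
    """A configuration value is invalid; the message names the offending field."""


class EmptyResultError(AlloscError):
    """A filtering step removed every record; raised instead of returning an empty object silently."""


class ParseError(AlloscError):
    """An input file is malformed."""
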