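"""Exception hierarchy shared by all pipeline stages."""


class PmnpipeError(Exception):
    """Base class for all pmnpipe errors."""


class ParseError(PmnpipeError):
    """A file could not be parsed; message names the offending line/cell."""


class ValidationError(PmnpipeError):
    """Parsed data violates a declared invariant."""


class ConfigurationError(PmnpipeError):
    """A configuration value is inconsistent or out of range."""
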