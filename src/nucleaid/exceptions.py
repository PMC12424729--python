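"""Exception hierarchy shared across the pipeline."""


class NucleaidError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NucleaidError):
    """A file violated its dialect contract; message names the offending line."""


class DataError(NucleaidError):
    """Inputs are well-formed but violate an operation's preconditions."""


class ConfigError(NucleaidError):
    """Invalid simulation or pipeline configuration."""
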