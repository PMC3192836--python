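"""Exception types shared across the pipeline."""


class MirdivError(Exception):
    """Base class for all package errors."""


class ConfigError(MirdivError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DimensionError(MirdivError, ValueError):
    """Mismatched gene/sample universes between inputs."""


class FormatError(MirdivError, ValueError):
    """Malformed input file; the message carries file, line and field."""
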