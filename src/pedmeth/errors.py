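"""Exception hierarchy shared across the pipeline.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class PedmethError(Exception):
    """Base class for all package errors."""


class ConfigError(PedmethError, ValueError):
    """Invalid configuration: bad thresholds, impossible sizing, missing stages."""


class DataError(PedmethError, RuntimeError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """Malformed input file; message carries file and line context."""
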