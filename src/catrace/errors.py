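"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class CaTraceError(Exception):
    """Base class for all catrace errors."""


class ConfigError(CaTraceError):
    """Invalid parameter or configuration value."""


class DataError(CaTraceError):
    """Malformed or unusable input data."""
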