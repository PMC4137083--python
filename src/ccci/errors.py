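"""Exception hierarchy.

Config problems (bad parameters) and data problems (malformed inputs) are
separated so the CLI can map them to distinct exit codes (2 and 3).
"""


class CcciError(Exception):
    """Base class for all package errors."""


class ConfigError(CcciError):
    """Invalid configuration value; the message names the offending field."""


class DataError(CcciError):
    """Malformed or inconsistent input data."""
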