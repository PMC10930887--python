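"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3.
"""


class AnsiaError(Exception):
    """Base class for all package errors."""


class ConfigError(AnsiaError, ValueError):
    """Invalid parameter or configuration value."""


class DataError(AnsiaError, ValueError):
    """Malformed, inconsistent or degenerate input data."""
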