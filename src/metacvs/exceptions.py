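"""Package-wide exception types, mapped to CLI exit codes."""


class MetaCVSError(Exception):
    """Base class for package errors."""


class ConfigError(MetaCVSError):
    """Invalid configuration or schema violation (CLI exit code 2)."""


class DataError(MetaCVSError):
    """Invalid or inconsistent dataset contents (CLI exit code 3)."""


class DivergenceError(MetaCVSError):
    """Training produced a non-finite loss (CLI exit code 4)."""
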