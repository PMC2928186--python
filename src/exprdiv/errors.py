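"""Exception hierarchy.

``ConfigError`` marks bad user-supplied configuration (CLI exit code 2);
``ValidationError`` marks malformed data encountered at run time (exit 1).
"""


class ExprDivError(Exception):
    """Base class for all package errors."""


class ConfigError(ExprDivError):
    """Invalid configuration (bad proportions, missing paths, alpha out of range)."""


class ValidationError(ExprDivError):
    """Malformed or inconsistent data (duplicate ids, shape mismatch, zero rows)."""
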