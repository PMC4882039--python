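"""Exception hierarchy.

Validation errors describe bad data (CLI exit code 2), configuration errors
describe bad settings (exit code 3); I/O problems propagate as OSError
(exit code 4).
"""


class LncrnapredError(Exception):
    """Base class for package errors."""


class ValidationError(LncrnapredError, ValueError):
    """Input data violates a contract (bad alphabet, shape mismatch, ...)."""


class ConfigurationError(LncrnapredError, ValueError):
    """Settings violate a contract (min_len > max_len, p out of range, ...)."""
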