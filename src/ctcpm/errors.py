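"""Exception hierarchy.

Validation errors signal data that violates a contract (asymmetry, missing
scores, bad labels); format errors signal malformed files; domain errors
signal arguments outside an operation's domain (e.g. ``n_folds > N``).
"""


class CtcpmError(Exception):
    """Base class for all package errors."""


class ValidationError(CtcpmError, ValueError):
    """Input data violates a contract."""


class FormatError(CtcpmError, ValueError):
    """A file does not conform to the expected layout."""


class DomainError(CtcpmError, ValueError):
    """An argument lies outside the operation's domain."""
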