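"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`ConfigError` -> 2,
:class:`FormatError` / :class:`IntegrityError` -> 3.
"""


class ExonSpliceError(Exception):
    """Base class for all package errors."""


class FormatError(ExonSpliceError):
    """A file could not be parsed (bad header, non-numeric cell, ...)."""


class IntegrityError(ExonSpliceError):
    """Parsed data violates a structural invariant (nesting, duplicates)."""


class ConfigError(ExonSpliceError):
    """Invalid configuration or parameter value."""
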