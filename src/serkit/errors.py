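"""Exception hierarchy.

All serkit errors derive from :class:`SerkitError` so callers (and the CLI)
can distinguish user/input problems from genuine bugs.
"""


class SerkitError(Exception):
    """Base class for all errors raised by serkit."""


class FormatError(SerkitError):
    """A file could not be parsed in the expected format."""


class ValidationError(SerkitError):
    """Input data violates a documented invariant."""


class SelectionError(SerkitError):
    """An atom-selection rule resolved to zero or multiple atoms."""


class DegenerateConformationError(SerkitError):
    """All points coincide; shape descriptors are undefined."""


class StateError(SerkitError):
    """An operation was applied in an invalid state (e.g. double normalization)."""


class ComparabilityError(SerkitError):
    """Entropy matrices built with different binning cannot be compared."""
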