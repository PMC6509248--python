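"""Exception hierarchy.

All package errors derive from :class:`LGBiplotError` so callers (and the CLI)
can distinguish user/data problems from genuine bugs.
"""


class LGBiplotError(Exception):
    """Base class for all errors raised by lgbiplot."""


class ConfigurationError(LGBiplotError):
    """Invalid configuration: missing columns, bad option values."""


class ParseError(LGBiplotError):
    """A field in an input file could not be parsed."""


class IntegrityError(LGBiplotError):
    """Data violates a structural invariant (e.g. duplicate keys)."""


class EmptySelectionError(LGBiplotError):
    """A selection (e.g. a year) matched no records."""


class DegenerateColumnError(LGBiplotError):
    """A column cannot be standardized (too few values or zero variance)."""


class MissingCellsError(LGBiplotError):
    """An operation that requires a complete matrix received missing cells."""


class DimensionError(LGBiplotError):
    """Matrix too small (or k too large) for the requested operation."""


class PreconditionError(LGBiplotError):
    """Model settings or inputs do not meet an operation's contract."""


class DegenerateAxisError(LGBiplotError):
    """The average-environment axis is undefined (zero mean vector)."""


class DegeneratePlacementError(LGBiplotError):
    """A zero-length placement vector has no direction to cluster on."""


class UnimputableError(LGBiplotError):
    """A row or column with no observed cells cannot be imputed."""


class LabelError(LGBiplotError):
    """A trial label does not decompose into location and year."""


class DesignError(LGBiplotError):
    """A simulation configuration produces an unusable trial design."""
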