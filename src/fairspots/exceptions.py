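"""Exception and warning hierarchy.

Everything raised deliberately by this package derives from
:class:`FairspotsError`, so callers (and the CLI) can distinguish contract
violations from genuine bugs.
"""


class FairspotsError(Exception):
    """Base class for all errors raised by fairspots."""


class FormatError(FairspotsError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(FairspotsError):
    """In-memory data violates a domain invariant."""


class SchemaError(FairspotsError):
    """Protected-attribute schemas are inconsistent or malformed."""


class UnknownIdError(FairspotsError):
    """A referenced individual id does not exist in the dataset."""


class EmptyInputError(FairspotsError):
    """An operation received an empty collection where content is required."""


class ParameterError(FairspotsError):
    """A parameter value is outside its admissible range."""


class ContractError(FairspotsError):
    """An operation was invoked outside its stated precondition."""


class BudgetExceededError(FairspotsError):
    """Exhaustive enumeration would exceed the configured subset budget."""


class DegenerateGeometryError(FairspotsError):
    """Spatial configuration admits no valid scan window (e.g. all points coincident)."""


class FairspotsWarning(UserWarning):
    """Non-fatal conditions (short hot-spot lists, undersized frontiers, ...)."""
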