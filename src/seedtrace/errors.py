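"""Exception hierarchy.

Every failure mode a caller can act on gets its own class; all inherit
from :class:`SeedTraceError` so shells can map them to exit codes in one place.
"""


class SeedTraceError(Exception):
    """Base class for all seedtrace errors."""


class ValidationError(SeedTraceError):
    """An entity or operation violates a type invariant."""


class DuplicateKeyError(ValidationError):
    """An entity with the same natural key but a different payload exists."""


class DuplicateNameError(DuplicateKeyError):
    """A seed lot with this name already exists."""


class UnknownLotError(SeedTraceError):
    """Referenced seed lot is not in the store."""


class UnknownParentError(UnknownLotError):
    """A parent seed lot named by an event does not exist."""


class UnknownEventError(SeedTraceError):
    """Referenced event is not in the store."""


class UnknownRelationError(SeedTraceError):
    """No relation links the given parent and child lots."""


class UnknownRecipientError(SeedTraceError):
    """Diffusion recipient (location or person) cannot be resolved."""


class MultiplicityError(ValidationError):
    """Wrong number of parents for the event kind."""


class CycleError(ValidationError):
    """Adding the relation would create a directed cycle."""


class DownstreamExistsError(SeedTraceError):
    """Event cannot be deleted alone: downstream events use its child lots."""


class FormatError(SeedTraceError):
    """Tabulated file is unreadable or lacks mandatory headers."""


class DateParseError(ValidationError):
    """Text is not a date in any accepted dialect."""


class IncompatibleSelectionError(SeedTraceError):
    """Template selection is empty or of the wrong object kind."""
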