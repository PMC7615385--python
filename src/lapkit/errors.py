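"""Exception hierarchy for the toolkit.

Every failure mode raised by lapkit derives from :class:`LapError`, so
callers (and the CLI) can catch one base class.  Validation of user
variable files never raises: problems are collected into a report
instead (see :mod:`lapkit.format_io`).
"""


class LapError(Exception):
    """Base class for all lapkit errors."""


# --- naming / file format -------------------------------------------------

class MalformedName(LapError):
    """A protocol name string does not follow the hyphenated grammar."""


class InvalidComponent(LapError):
    """A structured value violates one of its field invariants."""


class UnreadableFile(LapError):
    """A file exists but cannot be parsed in its claimed dialect."""


class UnknownDialect(LapError):
    """No reader is registered for the requested/inferred dialect."""


class DuplicateVariable(LapError):
    """The same variable name appears twice within one section."""


class IOFailure(LapError):
    """Filesystem write/read failed."""


# --- labware / deck -------------------------------------------------------

class UnknownLabware(LapError):
    """A labware api_name is not present in the catalog."""


class OutOfRange(LapError):
    """A height or volume lies outside the geometry's physical range."""


class SlotOccupied(LapError):
    """Attempt to load labware into a slot that already holds labware."""


class DeckFull(LapError):
    """No free slot remains on the deck."""


# --- planning -------------------------------------------------------------

class InvalidVolume(LapError):
    """A requested transfer volume is non-positive."""


class NoSuitablePipette(LapError):
    """No mounted pipette can partition the volume into valid chunks."""


class InvalidGeometry(LapError):
    """Tube geometry leaves no usable volume (fill limit below dead volume)."""


class CapacityExceeded(LapError):
    """More samples/volume requested than the labware can hold."""


# --- execution ------------------------------------------------------------

class NoTipError(LapError):
    """Aspirate/dispense attempted without a tip attached."""


class InsufficientVolume(LapError):
    """Aspiration would empty a well below zero (or a tube below its
    dead volume)."""


class OverfillError(LapError):
    """A dispense or initial fill would exceed the well/tube maximum."""


class VolumeOutOfRange(LapError):
    """Transfer volume outside the pipette's [min, max] working range."""


class InsufficientHeldVolume(LapError):
    """Dispense of more liquid than the pipette currently holds."""


class UnsupportedLabware(LapError):
    """An operation restricted to one labware type received another
    (e.g. z-tracked distribution from a tube that is not 15 mL conical)."""


class MissingMeasurement(LapError):
    """A sample lacks one of the measurements a selection rule needs."""


class BadWellId(LapError):
    """A well identifier does not exist on the given labware grid."""


class PlanExecutionError(LapError):
    """A plan step failed during simulated execution.

    Carries the underlying ``cause`` (one of the errors above), the
    ``state`` exactly as it stood before the failing step (failed steps
    mutate nothing) and the ``log`` of every successful step."""

    def __init__(self, message: str, cause: Exception, state, log):
        super().__init__(message)
        self.cause = cause
        self.state = state
        self.log = log
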