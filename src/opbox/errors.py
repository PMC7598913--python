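"""Exception hierarchy.

Everything raised on purpose derives from :class:`OpBoxError` so callers can
catch the package's own failures without swallowing programming errors.
"""


class OpBoxError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(OpBoxError, ValueError):
    """Invalid parameters, malformed configuration, or precondition failure."""


class DuplicateSubjectError(ValidationError):
    """The same subject id appears more than once in the subjects table."""


class UnknownBoxError(ValidationError):
    """A subject references a box id absent from the boxes table."""


class UnknownDeviceError(ValidationError):
    """A box references a device id that the acquisition backend does not expose."""


class ChannelCollisionError(ValidationError):
    """Two boxes claim the same channel index on the same device."""


class AliasingError(ValidationError):
    """A signal moves too fast for the sampling rate to represent it."""


class StateError(OpBoxError, RuntimeError):
    """Illegal session-state transition (double start, stop of inactive subject...)."""


class StreamIntegrityError(OpBoxError, RuntimeError):
    """A device chunk arrived with a gap or overlap in its sample index."""


class UndefinedMetricError(OpBoxError, ArithmeticError):
    """A metric has no defined value for this input (e.g. zero-RMS reference)."""


class UndefinedRiseTimeError(UndefinedMetricError):
    """The step response never crosses 90% of its post-step maximum."""


class NonMeasurableImpedanceError(UndefinedMetricError):
    """RMS through the series resistor is not below the direct RMS, so the
    divider formula would give a non-physical (negative or infinite) impedance."""


class CorruptRecordingError(OpBoxError, IOError):
    """Recording payload is truncated or not frame-aligned.

    ``byte_offset`` is the offset of the first byte that cannot be part of a
    complete frame.
    """

    def __init__(self, message: str, byte_offset: int):
        super().__init__(message)
        self.byte_offset = int(byte_offset)
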