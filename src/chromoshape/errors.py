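"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`ChromoshapeError`, so callers can catch pipeline problems without
swallowing programming errors.
"""


class ChromoshapeError(Exception):
    """Base class for all errors raised by chromoshape."""


class ParameterError(ChromoshapeError):
    """An invalid parameter value; the message names the offending field.

    Deliberately not a ValueError subclass: pydantic would swallow those in
    model validators and re-wrap them, hiding the package's own type.
    """


class InputError(ChromoshapeError, ValueError):
    """Invalid or inconsistent input data (missing channel, mixed bin grids...)."""


class FormatError(ChromoshapeError, ValueError):
    """An image file could not be interpreted (unreadable or ambiguous axes)."""


class PlacementError(ChromoshapeError, RuntimeError):
    """Cells could not be composited onto one field of view without overlap."""


class ShapeNotArcLikeError(ChromoshapeError, RuntimeError):
    """The DNA signal is too degenerate for the annular backbone model."""


class UsageError(ChromoshapeError, ValueError):
    """An operation was called in a way that makes no sense (e.g. distance
    between foci from different cells)."""
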