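"""Exception hierarchy for hipclear.

All geometric degeneracies raise :class:`DegenerateGeometryError` subclasses so
callers can distinguish "the input cannot support this operation" from plain
programming errors.
"""


class HipclearError(Exception):
    """Base class for all package-specific errors."""


class InputError(HipclearError):
    """Invalid or inconsistent user input (missing labels, bad config, ...)."""


class DegenerateGeometryError(HipclearError):
    """A geometric construction is undefined for this input (coplanar sphere
    points, coincident landmarks, parallel axes, coincident centres, ...)."""


class AmbiguousAxisError(DegenerateGeometryError):
    """Point set has no dominant principal direction."""


class NoMeasurementError(HipclearError):
    """No usable plane / frame was available to produce a measurement."""
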