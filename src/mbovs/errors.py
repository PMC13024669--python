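"""Exception hierarchy for mbovs.

All package errors derive from :class:`MbOvsError` so callers can catch one
base class; validation errors additionally derive from ``ValueError``.
"""


class MbOvsError(Exception):
    """Base class for all mbovs errors."""


class InvalidSpecError(MbOvsError, ValueError):
    """A pulse or sequence specification violates its invariants."""


class InvalidGeometryError(MbOvsError, ValueError):
    """Slab or phantom geometry is inconsistent (overlaps, zero thickness)."""


class ResolutionError(InvalidSpecError):
    """Raster time too coarse for the requested pulse duration."""


class TimingError(MbOvsError, RuntimeError):
    """A sequence event does not fit in the available timing gap."""


class UndefinedMetricError(MbOvsError, ValueError):
    """A metric is undefined for the given inputs (e.g. zero baseline)."""


class DegenerateProfileError(MbOvsError, ValueError):
    """A slab profile lacks the crossings needed to compute a metric."""
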