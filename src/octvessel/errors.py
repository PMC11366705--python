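"""Exception hierarchy.

Everything raised on bad input or failed detection derives from
:class:`OCTVesselError`, which itself subclasses ``ValueError`` so callers
that only know the standard library still catch sensible things.
"""


class OCTVesselError(ValueError):
    """Base class for all package-specific errors."""


class InvalidSpecError(OCTVesselError):
    """A synthetic-phantom or cohort specification violates its invariants."""


class ProfileBoundsError(OCTVesselError):
    """A measurement line leaves the image raster."""


class BandDetectionError(OCTVesselError):
    """The two vessel-wall bands could not be located on a profile.

    Mirrors the manual quality gate of the measurement protocol: profiles
    that do not clearly show both walls are rejected rather than measured.
    """


class DegenerateFlankError(OCTVesselError):
    """A flank is flat (no intensity range or no nonzero chord slope)."""


class EdgeLocalizationError(OCTVesselError):
    """The half-level crossing fell outside the flank under analysis."""


class EdgeOrderingError(OCTVesselError):
    """Detected edges are not in outer-upper < inner-upper < inner-lower < outer-lower order."""


class InfiniteStatisticError(OCTVesselError):
    """A test statistic is undefined because the relevant variance is zero."""


class SchemaError(OCTVesselError):
    """A cohort table is missing required columns or has malformed labels."""
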