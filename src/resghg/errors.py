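"""Exception hierarchy.

All package errors derive from :class:`ResGHGError` so callers can catch a
single base class.  CLI exit codes: schema/validation errors exit 2, numerical
failures exit 3.
"""


class ResGHGError(Exception):
    """Base class for all package errors."""


class SchemaError(ResGHGError):
    """A file or table does not conform to its documented schema."""

    def __init__(self, message, *, source=None, row=None, field=None):
        self.source = source
        self.row = row
        self.field = field
        loc = []
        if source is not None:
            loc.append(str(source))
        if row is not None:
            loc.append(f"row {row}")
        if field is not None:
            loc.append(f"field {field!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)


class NumericalError(ResGHGError):
    """Base class for numerical failures (exit code 3)."""


# --- emission-factor table ---------------------------------------------------

class UnknownZone(ResGHGError):
    """Climate-zone label outside the closed six-element set."""


class MissingEF(ResGHGError):
    """The (zone, pathway) cell is absent from the emission-factor table."""


# --- core emissions ----------------------------------------------------------

class ZeroArea(ResGHGError):
    """Non-run-of-river reservoir with area <= 0."""


class MissingFeature(ResGHGError):
    """An empirical-model feature name resolves to no record field."""


class NonFiniteFlux(NumericalError):
    """A link inverse overflowed or produced a non-finite flux."""


class MissingClassFlux(ResGHGError):
    """A land-cover class with positive fraction has no pre-impoundment flux."""


class ZeroGeneration(ResGHGError):
    """Emission intensity requested for an asset with zero generation."""


# --- calibration -------------------------------------------------------------

class EmptySubset(ResGHGError):
    """No calibration samples remain after subsetting."""


class DegenerateCell(ResGHGError):
    """A zone vanished from most bootstrap resamples; margin unreliable."""


class RankDeficient(NumericalError):
    """Collinear gross-flux columns in the net-parameter regression."""


# --- delineation -------------------------------------------------------------

class AllMasked(ResGHGError):
    """Elevation grid has no unmasked cells."""


class NoRiver(ResGHGError):
    """No river cell exceeds the accumulation threshold."""


class NoWaterAtDam(ResGHGError):
    """No water-class pixel at or adjacent to the dam cell."""


class EmptyMask(ResGHGError):
    """Zonal statistics requested over an empty mask."""


class BrokenTopology(ResGHGError):
    """Basin traversal met a basin without a downstream link inside the ROI."""


# --- planner -----------------------------------------------------------------

class CyclicInput(ResGHGError):
    """Dam-node graph contains a cycle."""


class MultipleOutlets(ResGHGError):
    """Dam-node graph has more than one outlet (root)."""


class EmptyTree(ResGHGError):
    """Planner invoked on a tree without assets."""


class NonFiniteMetric(NumericalError):
    """An asset metric is NaN or infinite."""


class SeriesTooShort(ResGHGError):
    """Generation series too short for a stable percentile."""


# --- surrogate ---------------------------------------------------------------

class TooFewRows(ResGHGError):
    """Not enough training rows for the surrogate."""


class NonFiniteTarget(NumericalError):
    """Target vector contains NaN or infinite values."""


class EmptyBackground(ResGHGError):
    """Breakdown attribution requested with an empty background sample."""


class RankTooLow(NumericalError):
    """Attribution matrix rank below the requested embedding dimension."""


# --- synthetic ---------------------------------------------------------------

class TooManyDams(ResGHGError):
    """More dams requested than the synthetic river network can host."""
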