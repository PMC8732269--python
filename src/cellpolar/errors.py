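"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`CellPolarError`, so batch drivers
can catch one type, log the failing stage, and continue with the next cell.
"""


class CellPolarError(Exception):
    """Base class for all cellpolar errors."""


class UsageError(CellPolarError, ValueError):
    """Invalid arguments or malformed inputs (shapes, names, missing files)."""


class InvalidGeometryError(CellPolarError):
    """A phantom geometry specification violates its invariants."""


class DegenerateGeometryError(CellPolarError):
    """Masks/center do not support the polar sweep (e.g. a ray misses the
    nucleus, the centroid falls outside a non-convex nucleus, or
    r_ne >= r_edge at some angle)."""


class EmptySignalError(CellPolarError):
    """Zero total fluorescence on the requested domain; no PMF exists."""


class PrecisionError(CellPolarError):
    """Numerical quadrature failed to converge to the requested tolerance."""


class StageError(CellPolarError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
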