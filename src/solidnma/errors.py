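"""Exception hierarchy."""


class SolidNMAError(Exception):
    """Base class for all package errors."""


class FormatError(SolidNMAError):
    """Unreadable or malformed input file."""


class EmptyStructureError(SolidNMAError):
    """A structure or model with no atoms."""


class TooFewNodesError(SolidNMAError):
    """A node selection too small to build a tetrahedral solid (< 4 points)."""


class EmptySelectionError(SolidNMAError):
    """A selection (e.g. density threshold) that keeps no points."""


class DegenerateGeometryError(SolidNMAError):
    """Coplanar/duplicate points where a non-degenerate simplex is required."""


class EmptyShapeError(SolidNMAError):
    """An alpha filter that removes every tetrahedron."""


class BracketingError(SolidNMAError):
    """A target value outside the attainable range of a search."""


class CalibrationError(SolidNMAError):
    """Degenerate data for a least-squares calibration."""


class UnderConstrainedError(SolidNMAError):
    """A static solve whose reduced stiffness is singular (free rigid motion)."""


class SolverError(SolidNMAError):
    """Eigen- or linear-solver failure."""
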