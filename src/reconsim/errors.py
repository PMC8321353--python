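"""Exception hierarchy shared across the package."""


class ReconsimError(Exception):
    """Base class for all package-specific errors."""


class STLFormatError(ReconsimError):
    """Raised for malformed STL files (bad header, count/byte-length mismatch)."""


class MeshSpecError(ReconsimError):
    """Raised when a synthetic-site specification violates its invariants."""


class DegenerateGeometryError(ReconsimError):
    """Raised for degenerate geometric configurations (collinear vertices,
    up-hint parallel to the viewing axis, rays parallel to a target plane)."""


class ProjectionDomainError(ReconsimError):
    """Raised when a point at or behind the aperture plane is projected."""


class GeometryError(ReconsimError):
    """Raised when a polygon boolean result has invalid ring topology."""


class FitError(ReconsimError):
    """Raised when a decay fit fails to converge; carries the best attempt."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
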