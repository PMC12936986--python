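"""Exception hierarchy for the limbmark pipeline."""


class LimbmarkError(Exception):
    """Base class for all limbmark errors."""


class MeshFormatError(LimbmarkError):
    """Unreadable or unsupported mesh file."""


class MeshValidationError(LimbmarkError):
    """Mesh violates a structural invariant (empty, bad indices, ...)."""


class EmptyRegionError(LimbmarkError):
    """Requested label/region contains no voxels or vertices."""


class LandmarkParseError(LimbmarkError):
    """Malformed landmark JSON."""


class IncompleteLandmarkError(LimbmarkError):
    """A required landmark or dependency is missing; names the acronym."""


class DegenerateGeometryError(LimbmarkError):
    """Geometrically degenerate input (coplanar sphere points, parallel axes...)."""


class AlignmentError(LimbmarkError):
    """Procrustes / rigid alignment failure on degenerate shapes."""


class ConvergenceError(LimbmarkError):
    """Iterative fit diverged; carries diagnostics in ``details``."""

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details or {}


class GridMismatchError(LimbmarkError):
    """Two label volumes do not share shape and affine."""


class UndefinedMetricError(LimbmarkError):
    """Metric undefined for this input (empty mask, zero variance, ...)."""
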