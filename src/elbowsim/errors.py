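"""Exception hierarchy shared across the package."""


class ElbowSimError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(ElbowSimError):
    """Input file could not be parsed as a surface mesh."""


class EmptyMeshError(ElbowSimError):
    """Mesh has no faces."""


class DegenerateGeometryError(ElbowSimError):
    """Geometric construction is ill-posed (collinear landmarks, point inside obstacle...)."""


class ParameterError(ElbowSimError):
    """A physical parameter is outside its admissible range."""


class CalibrationError(ElbowSimError):
    """Zero-load-length calibration could not be performed."""


class StateError(ElbowSimError):
    """Operation requires state (poses, calibration) that is missing."""


class ShapeError(ElbowSimError):
    """Array/series shapes or channel sets do not match."""


class TrajectoryError(ElbowSimError):
    """Requested motion exceeds the model's geometric limits."""


class SolverError(ElbowSimError):
    """Forward-dynamics integration diverged or produced non-finite state."""


class UndefinedCorrelationError(ElbowSimError):
    """Pearson correlation undefined (zero-variance input)."""
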