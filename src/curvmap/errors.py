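"""Exception hierarchy shared across the package."""


class CurvmapError(Exception):
    """Base class for all package errors."""


class StructureFormatError(CurvmapError):
    """A structure or mesh file could not be parsed."""


class EmptyStructureError(CurvmapError):
    """A structure with zero atoms was supplied where atoms are required."""


class TrajectoryConsistencyError(CurvmapError):
    """Frames of a trajectory disagree in atom count or identity."""


class AtomTypingError(CurvmapError):
    """An atom could not be resolved against a parameter table (strict mode)."""


class AnnotationError(CurvmapError):
    """A region definition references chains/residues absent from the structure."""


class MeshFormatError(CurvmapError):
    """A surface-mesh file violates its dialect."""


class ParameterError(CurvmapError):
    """An invalid numerical parameter was supplied."""


class ConsistencyError(CurvmapError):
    """Two objects that must share atom/point identity do not."""


class MetricError(CurvmapError):
    """A regression metric is undefined for the given data."""


class EmptySelectionError(CurvmapError):
    """Feature filtering removed every column."""
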