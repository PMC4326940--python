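"""Exception hierarchy for micromorph."""


class MicromorphError(Exception):
    """Base class for all micromorph errors."""


class ParameterError(MicromorphError, ValueError):
    """An argument is outside its valid range."""


class TraceFormatError(MicromorphError, ValueError):
    """An SWC file or in-memory trace violates the trace invariants."""


class GenerationError(MicromorphError, ValueError):
    """The synthetic scene cannot be generated from the given settings."""


class RenderError(MicromorphError, ValueError):
    """A scene cannot be rasterized at the requested voxel geometry."""


class NoCellsError(MicromorphError, ValueError):
    """A stack contains no foreground above the threshold."""


class DegenerateGeometryError(MicromorphError, ValueError):
    """Too few or collinear points for a planar hull."""


class GeometryError(MicromorphError, ValueError):
    """Image geometry incompatible with the requested analysis window."""


class UndefinedCoverageError(MicromorphError, ZeroDivisionError):
    """Coverage volume requested for a cell with zero volume."""
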