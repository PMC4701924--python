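"""Exception hierarchy for voxelgraph.

Every error raised on a user-facing code path derives from
:class:`VoxelGraphError`, so callers (including the CLI) can catch one type.
"""


class VoxelGraphError(Exception):
    """Base class for all voxelgraph errors."""


class ValidationError(VoxelGraphError):
    """An input value violates a documented precondition."""


class GeometryError(VoxelGraphError):
    """Image and mask grids (dims or affines) do not agree."""


class FormatError(VoxelGraphError):
    """A file is not in the expected format (e.g. a 3D image where 4D is required)."""


class CapacityError(VoxelGraphError):
    """A memory/tile budget is too small to hold even one row block."""


class EdgeListParseError(VoxelGraphError):
    """An edge-list line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class ConvergenceError(VoxelGraphError):
    """An iterative solver did not converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


class StatisticUndefinedError(VoxelGraphError):
    """The edge-density statistic S = log E / log K is undefined (K <= 1 or E = 0)."""


class AlignmentError(VoxelGraphError):
    """Subject tables do not share the same voxel index map."""


class ThresholdRangeError(VoxelGraphError):
    """No threshold on the search grid attains the requested edge density."""
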