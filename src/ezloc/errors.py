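"""Exception hierarchy shared across the pipeline stages."""


class EzlocError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EzlocError):
    """Input file unreadable or not in a supported format."""


class DimensionalityError(FormatError):
    """Volume has the wrong number of dimensions; message names the shape."""


class GridMismatchError(EzlocError):
    """Two volumes are not on the same voxel grid (shape and/or affine)."""


class GeometryError(EzlocError):
    """Geometric precondition violated (source outside shell, blob outside brain, ...)."""


class ParameterError(EzlocError):
    """Invalid parameter value."""


class DegenerateInputError(EzlocError):
    """Input is degenerate for the requested operation (e.g. zero variance)."""


class ConvergenceError(EzlocError):
    """Iterative procedure failed to converge.

    Carries the best-so-far result in ``payload`` so callers can inspect it.
    """

    def __init__(self, message, payload=None):
        super().__init__(message)
        self.payload = payload
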