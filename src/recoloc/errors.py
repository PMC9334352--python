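"""Exception hierarchy shared across the package."""


class RecolocError(Exception):
    """Base class for all package errors."""


class ParameterError(RecolocError, ValueError):
    """Invalid configuration or function parameter."""


class SchemaError(RecolocError, ValueError):
    """Input file does not match the expected column schema."""


class EmptyInputError(RecolocError, ValueError):
    """An operation received or produced an empty point set."""


class DimensionalityError(RecolocError, ValueError):
    """2D/3D mismatch or unsupported dimensionality."""


class DegenerateGeometryError(RecolocError, ValueError):
    """Seed geometry is degenerate (collinear/coplanar or duplicated)."""


class EmptyAnalysisError(RecolocError, ValueError):
    """No bounded Voronoi regions survive the edge discard."""


class GenerationError(RecolocError, RuntimeError):
    """A simulation constraint could not be satisfied."""
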