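"""Exception hierarchy shared across the package."""


class RwlrError(Exception):
    """Base class for all package errors."""


class ParameterError(RwlrError, ValueError):
    """A function argument is outside its documented domain."""


class InputError(RwlrError, ValueError):
    """Input data violate a structural precondition (gaps, NaNs, shape)."""


class FitError(RwlrError, RuntimeError):
    """A statistical fit could not be carried out."""


class DegenerateTriangleError(FitError):
    """Dry edge does not lie strictly above the wet edge."""


class GeometryError(RwlrError, ValueError):
    """A geometry does not intersect the grid, or a mask is degenerate."""


class InterfaceError(RwlrError, ValueError):
    """Two gridded inputs are not compatible (CRS, shape, alignment)."""


class IdentificationError(FitError):
    """A path model is not identified for the data at hand."""


class GraphError(RwlrError, ValueError):
    """A path specification contains a cycle or unknown variable."""


class ConfigError(RwlrError, ValueError):
    """A run configuration failed validation."""


class SampleSizeError(RwlrError, ValueError):
    """Too few observations for the requested test."""
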