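"""Exception hierarchy.

Every error raised on a bad input or a failed computation derives from
:class:`ChromameshError` so callers (and the CLI) can catch one base class.
"""


class ChromameshError(Exception):
    """Base class for all package errors."""


class ParseError(ChromameshError):
    """A file could not be parsed (malformed record, bad field)."""


class StructuralError(ChromameshError):
    """Inputs are individually valid but mutually inconsistent."""


class GeometryError(ChromameshError):
    """Degenerate geometry: collinear/duplicate landmarks, bad polygon."""


class ConvergenceError(ChromameshError):
    """An iterative fit failed to converge within its iteration budget."""


class ParameterError(ChromameshError):
    """An argument is outside its documented domain."""


class SamplingError(ChromameshError):
    """A sampling location falls entirely outside the raster."""


class StatError(ChromameshError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
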