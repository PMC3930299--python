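"""Exception hierarchy shared across the package."""


class AneuscaleError(Exception):
    """Base class for all package-specific errors."""


class STLParseError(AneuscaleError, ValueError):
    """Raised when an STL file cannot be parsed; the message names the
    offending byte offset (binary) or line number (ASCII)."""


class EmptyMeshError(AneuscaleError, ValueError):
    """Raised when an operation receives or produces a mesh with no faces."""


class GeometryError(AneuscaleError, ValueError):
    """Raised for geometric failures: a plane missing the mesh, an open
    intersection chain, a degenerate normal, a seed on the wrong side."""


class FeasibilityError(AneuscaleError, ValueError):
    """Raised in strict mode when scaling parameters would collapse or
    invert the sac (a non-positive scale factor somewhere in the sac)."""
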