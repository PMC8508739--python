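"""Exception types shared across the analysis stages."""


class UnfoldscopeError(Exception):
    """Base class for all package-specific errors."""


class GridError(UnfoldscopeError, ValueError):
    """Time-channel grids of decays and IRF are incompatible."""


class DomainError(UnfoldscopeError, ValueError):
    """Parameter outside its physical domain (e.g. non-positive lifetime)."""


class InsufficientDataError(UnfoldscopeError, ValueError):
    """Not enough signal in the data to attempt a fit."""


class RangeError(UnfoldscopeError, ValueError):
    """Requested wavelength/value outside the tabulated range."""


class SchemaError(UnfoldscopeError, ValueError):
    """A table or report is missing a required column/field."""


class GeometryError(UnfoldscopeError, ValueError):
    """Degenerate geometry (collinear ring atoms, coincident centers)."""


class IncompleteResidueError(UnfoldscopeError, ValueError):
    """A residue lacks atoms required for the requested computation."""


class ResidueLookupError(UnfoldscopeError, KeyError):
    """Requested residue not present in the structure."""


class PdbParseError(UnfoldscopeError, ValueError):
    """Malformed mandatory columns in a coordinate file."""


class PlacementError(UnfoldscopeError, RuntimeError):
    """Synthetic-structure atom placement failed after retries."""
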