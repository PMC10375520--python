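"""Exception hierarchy for shiftmaps."""


class ShiftmapsError(Exception):
    """Base class for all shiftmaps errors."""


class FormatError(ShiftmapsError):
    """A file could not be parsed (CIF, CSV, volumetric)."""


class ValidationError(ShiftmapsError):
    """Input data violates an invariant (bad element, uncertainty <= 0, ...)."""


class GeometryError(ShiftmapsError):
    """Degenerate geometry: near-zero cell volume, collinear anchors, ..."""


class ConfigurationError(ShiftmapsError):
    """Inconsistent user configuration (anchor outside descriptor depth, ...)."""


class InsufficientMatchesError(ShiftmapsError):
    """Fewer database matches than the number of environments requested."""


class AssignmentError(ShiftmapsError):
    """A query site cannot be located in a candidate structure."""


class UsageError(ShiftmapsError):
    """Unsupported option value (unknown volumetric format, ...)."""
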