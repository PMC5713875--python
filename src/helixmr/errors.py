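"""Exception hierarchy shared across the package."""


class HelixMRError(Exception):
    """Base class for all package errors."""


class ValidationError(HelixMRError):
    """Input violates a documented precondition."""


class PdbFormatError(HelixMRError):
    """Unparseable coordinate-file record; message names the line number."""


class EmptyStructureError(HelixMRError):
    """A coordinate file or model contained no usable atoms."""


class ChainLookupError(HelixMRError, KeyError):
    """A requested chain id is absent from the model."""


class DegenerateGeometryError(HelixMRError):
    """Coordinates are numerically degenerate for the requested operation."""
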