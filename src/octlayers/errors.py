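"""Exception hierarchy.

All package errors derive from :class:`OctLayersError` so callers can catch
one base class. Validation-type errors also derive from ``ValueError``.
"""


class OctLayersError(Exception):
    """Base class for all errors raised by octlayers."""


class ValidationError(OctLayersError, ValueError):
    """Invalid parameter, specification, or domain value."""


class GeometryMismatchError(ValidationError):
    """Stored data does not match the declared scan geometry."""


class FormatError(OctLayersError):
    """A file could not be parsed in the expected format."""


class SchemaError(FormatError):
    """A table is missing required columns or has malformed values."""


class BoundsError(ValidationError):
    """An index, band, or position lies outside the valid grid."""


class SegmentationFailureError(OctLayersError):
    """An interface could not be detected (empty band or degenerate image)."""

    def __init__(self, message: str, interface_index: int | None = None):
        super().__init__(message)
        self.interface_index = interface_index


class InsufficientDataError(OctLayersError):
    """Too few assigned pixels / records to compute the requested quantity."""


class CollinearityError(OctLayersError):
    """Rank-deficient regression design matrix."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class CategoryError(ValidationError):
    """A categorical field holds a value outside its allowed levels."""
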