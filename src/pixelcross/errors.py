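"""Exception hierarchy for polygon cross-matching."""


class PixelCrossError(Exception):
    """Base class for all package errors."""


class InvalidPolygonError(PixelCrossError):
    """Ring is degenerate, self-intersecting, or otherwise not a simple polygon."""


class DegenerateScalingError(PixelCrossError):
    """Rounded ring collapsed (< 3 distinct vertices or zero area) at this factor."""


class UnsupportedGeometryError(PixelCrossError):
    """Input record is not a single exterior ring (holes, multipolygons...)."""


class ConfigError(PixelCrossError):
    """Invalid run configuration."""


class FormatError(PixelCrossError):
    """Unparseable input file; message carries the record/line locus."""
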