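"""Typed exceptions raised across the toolkit.

Every malformed input maps to one of these; nothing falls back to a silent
default.
"""


class CIHError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(CIHError):
    """Malformed or inconsistent index configuration."""


class PanelSchemaError(CIHError):
    """Panel CSV does not match the configured indicator schema."""


class PanelParseError(CIHError):
    """Non-numeric cell (or similar) in the indicator panel."""


class ImputationError(CIHError):
    """A missing cell has neither a hot-deck donor nor a reference value."""


class DegenerateIndicatorError(CIHError):
    """An indicator column is constant, so goalposts collapse."""


class CorrelationError(CIHError):
    """Correlation undefined (constant column or too few units)."""


class WeightsFormatError(CIHError):
    """Spatial weights file (GAL or edge list) is malformed."""


class ZeroVarianceError(CIHError):
    """Spatial statistics are undefined on a constant surface."""


class GeoJoinError(CIHError):
    """Panel units missing from the GeoJSON being annotated."""
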