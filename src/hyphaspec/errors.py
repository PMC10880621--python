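"""Exception hierarchy shared across hyphaspec modules."""


class HyphaspecError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HyphaspecError):
    """A file does not conform to the documented on-disk layout."""


class ValidationError(HyphaspecError):
    """An in-memory object violates a structural invariant."""


class RangeError(HyphaspecError):
    """A wavenumber or value falls outside the supported span."""


class GeometryError(HyphaspecError):
    """Scene or cut geometry is inconsistent with the image extent."""


class ConfigurationError(HyphaspecError):
    """Mutually inconsistent simulation/analysis parameters."""


class DegeneracyError(HyphaspecError):
    """A matrix or reference set is rank-deficient / all-zero."""


class NormalizationError(HyphaspecError):
    """Anchor-peak normalization is impossible (signal below floor)."""


class AmbiguousLabelingError(HyphaspecError):
    """Semantic zone ranking is tied beyond tolerance."""


class InsufficientSupportError(HyphaspecError):
    """Too few pixels/points to compute a statistic."""


class SelectionError(HyphaspecError):
    """Pixel selection near radial cuts came up empty."""
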