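"""Exception hierarchy shared across the pipeline stages."""


class GIScreenError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GIScreenError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(GIScreenError):
    """Input data violates a structural invariant (e.g. duplicate ids)."""


class ConfigurationError(GIScreenError):
    """A configuration value is out of range or mutually inconsistent."""


class CoverageError(GIScreenError):
    """Stratified cell lines do not overlap the dataset being screened."""


class InsufficientDataError(GIScreenError):
    """Too few observations to run a test or a fit."""


class DesignError(GIScreenError):
    """An experimental design does not span the range a fit requires."""


class GeometryError(GIScreenError):
    """Titration geometry is physically impossible (e.g. overfilled cell)."""


class NormalizationError(GIScreenError):
    """Viability normalization references are degenerate."""
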