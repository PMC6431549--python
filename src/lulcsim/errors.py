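"""Exception hierarchy shared across the package."""


class LulcsimError(Exception):
    """Base class for all package errors."""


class RasterFormatError(LulcsimError):
    """A raster file could not be parsed as a single-band integer grid."""


class ComparabilityError(LulcsimError):
    """Two landscapes do not share shape, cell size and nodata footprint."""


class EstimationError(LulcsimError):
    """A statistical quantity could not be estimated from the given data."""


class AnnualizationError(LulcsimError):
    """A period transition matrix has no usable yearly root."""


class ScenarioInfeasibleError(LulcsimError):
    """Scenario multipliers push a row's off-diagonal mass to 1 or beyond."""


class ConfigurationError(LulcsimError):
    """A run configuration or driver update rule is inconsistent."""
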