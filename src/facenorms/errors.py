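"""Exception hierarchy shared across the package."""


class FacenormsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FacenormsError):
    """Invalid definition, template mismatch, or bad configuration value."""


class DegenerateGeometryError(FacenormsError):
    """Too few / collinear landmarks to define the requested geometry."""


class FitError(FacenormsError):
    """Curve fitting failed (insufficient points or non-convergence)."""


class SampleSizeError(FacenormsError):
    """A stratum is below the configured minimum number of usable records."""


class CiError(FacenormsError):
    """Bootstrap confidence-interval estimation failed."""


class FormatError(FacenormsError):
    """A file does not conform to the expected dialect or schema."""


class SchemaVersionError(FormatError):
    """A serialized artifact was written by an incompatible schema version."""


class UsageError(FacenormsError):
    """The caller violated an interface contract (e.g. sex mismatch)."""
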