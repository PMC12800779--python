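"""Exception hierarchy shared across the package."""


class EndemapperError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EndemapperError):
    """A column mapping, config file or option set is unusable."""


class ParameterError(EndemapperError, ValueError):
    """A numeric parameter is outside its admissible range."""


class GeometryError(EndemapperError):
    """A polygon or point set is geometrically invalid."""


class IntegrityError(EndemapperError):
    """Inputs to an operation are mutually inconsistent."""


class ValidationError(EndemapperError):
    """A data value violates its domain contract."""
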