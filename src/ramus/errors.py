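"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument is outside its admissible range."""


class GeometryError(ValueError):
    """Sources or sensors violate the spherical-head geometry."""


class DimensionError(ValueError):
    """Array shapes are inconsistent with each other."""


class DegenerateDataError(ValueError):
    """The requested simulation would produce identically-zero data."""


class NumericError(RuntimeError):
    """A numerical routine produced non-finite values or failed to converge."""


class ConfigError(ValueError):
    """An experiment configuration is invalid or unknown."""
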