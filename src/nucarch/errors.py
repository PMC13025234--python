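"""Exception types shared across the package."""


class NucarchError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(NucarchError):
    """Image geometry is invalid or inconsistent with the data."""


class CrowdedFieldError(NucarchError):
    """Object placement failed: the field is too crowded for the request."""


class ConfigError(NucarchError):
    """A run configuration is structurally invalid."""

    def __init__(self, message, keys=()):
        self.keys = tuple(keys)
        if self.keys:
            message = f"{message}: {', '.join(map(str, self.keys))}"
        super().__init__(message)


class NormalizationError(NucarchError):
    """Array normalization is impossible (e.g. all-zero signals)."""


class MissingDataError(NucarchError):
    """A required record or group of records is absent."""
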