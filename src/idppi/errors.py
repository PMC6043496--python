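"""Exception hierarchy shared across the package."""


class IdppiError(Exception):
    """Base class for all package-specific errors."""


class InvalidSequenceError(IdppiError, ValueError):
    """A sequence cannot be encoded (too short, empty, or unsalvageable)."""


class ConfigurationError(IdppiError, ValueError):
    """A scale, config object or search space is malformed."""


class InfeasibleSamplingError(IdppiError, RuntimeError):
    """Negative sampling cannot satisfy the requested ratio without duplicates."""

    def __init__(self, message: str, attainable: int | None = None):
        super().__init__(message)
        self.attainable = attainable


class LeakageError(IdppiError, RuntimeError):
    """A train/test split violates the component-disjoint contract."""


class SchemaMismatchError(IdppiError, ValueError):
    """Feature schema at predict time differs from the schema at fit time."""
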