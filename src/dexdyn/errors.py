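"""Exception and warning types shared across the package."""


class DexdynError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DexdynError, ValueError):
    """A simulation or analysis parameter is outside its valid range."""


class SchemaError(DexdynError, ValueError):
    """A file or table violates its documented schema or an invariant."""


class ConsistencyError(DexdynError, ValueError):
    """Two inputs that must agree (e.g. counts vs sample sheet) do not."""


class ConfigurationError(DexdynError, ValueError):
    """An experiment configuration is unusable (e.g. ambiguous DNA keys)."""


class DegenerateSampleError(DexdynError, ValueError):
    """A sample cannot be normalized (e.g. all-zero counts)."""


class NonIdentifiableError(DexdynError, ValueError):
    """A model term cannot be estimated (e.g. constant covariate)."""


class DependencyError(DexdynError, RuntimeError):
    """A pipeline stage was requested before its upstream artifacts exist."""


class DexdynWarning(UserWarning):
    """Base class for package warnings."""
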