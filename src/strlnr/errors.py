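"""Exception types shared across the package."""


class StrlnrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StrlnrError):
    """A run configuration or input file reference is invalid."""


class ValidationError(StrlnrError):
    """An input record violates a documented invariant."""


class LocusError(StrlnrError):
    """A single locus cannot be processed; other loci may still succeed."""


class BackendError(StrlnrError):
    """An external alignment backend failed."""
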