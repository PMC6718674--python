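"""Exception hierarchy shared across the package."""


class CotwinError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CotwinError):
    """Invalid or inconsistent configuration."""


class ValidationError(CotwinError):
    """Input data violates a documented contract (range, shape, uniqueness)."""


class ConsistencyError(CotwinError):
    """Cross-artifact mismatch (e.g. matrix probe absent from manifest)."""


class InvalidRegionError(CotwinError):
    """A genomic region with impossible coordinates."""
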