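"""Exception hierarchy shared across the package."""


class DauerxError(Exception):
    """Base class for all package errors."""


class FormatError(DauerxError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(DauerxError):
    """Parsed content violates a domain invariant (e.g. negative intensity)."""


class EstimationError(DauerxError):
    """Too little usable data to estimate model parameters."""


class NormalizationError(DauerxError):
    """Normalization preconditions not met (e.g. too few spike probes)."""


class ConfigError(DauerxError):
    """Invalid pipeline or simulation configuration."""
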