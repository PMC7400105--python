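"""Exception hierarchy for the etdrift package."""


class ETDriftError(Exception):
    """Base class for all package-specific errors."""


class DataError(ETDriftError):
    """Malformed, inconsistent, or insufficient measurement data."""


class ConfigError(ETDriftError):
    """Invalid configuration (simulation or run options)."""


class FitError(ETDriftError):
    """A model could not be fitted from the supplied data."""
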