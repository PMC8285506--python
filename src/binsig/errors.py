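"""Exception hierarchy shared across the package."""


class BinsigError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BinsigError, ValueError):
    """Invalid configuration value; message names the offending field(s)."""


class FormatError(BinsigError, ValueError):
    """Malformed or inconsistent input file."""


class AnalysisError(BinsigError, ValueError):
    """Precondition of an analysis operation violated (empty groups,
    missing genes, degenerate inputs)."""
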