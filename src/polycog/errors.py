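"""Exception hierarchy for polycog."""


class PolycogError(Exception):
    """Base class for package errors."""


class ConfigError(PolycogError, ValueError):
    """Invalid configuration value."""


class FormatError(PolycogError, ValueError):
    """Malformed input file or table."""


class DegenerateDataError(PolycogError, ValueError):
    """Input is structurally valid but degenerate for the requested operation
    (zero variance, rank deficiency, single-class binary, ...)."""
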