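"""Exception hierarchy for turnoverscan."""


class TurnoverScanError(Exception):
    """Base class for all package errors."""


class FormatError(TurnoverScanError):
    """Malformed input table, tree or matrix."""


class ConfigError(TurnoverScanError):
    """Invalid run configuration."""
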