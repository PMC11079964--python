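"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to
exit code 1.
"""


class WmcppError(Exception):
    """Base class for package errors."""


class ConfigError(WmcppError):
    """Invalid configuration (bad schema, missing channel, bad window)."""


class DataError(WmcppError):
    """Invalid or unusable data."""


class ContainerFormatError(DataError):
    """Malformed on-disk container (bad header field, payload size, kind)."""


class SimulationError(DataError):
    """Synthetic-data generation failed (e.g. decision-time redraw exhausted)."""
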