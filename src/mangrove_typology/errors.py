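"""Exception hierarchy shared by all pipeline stages."""


class MangroveTypologyError(Exception):
    """Base class for all package errors."""


class ConfigError(MangroveTypologyError, ValueError):
    """Invalid configuration value."""


class IOFormatError(MangroveTypologyError, IOError):
    """Unreadable or unsupported file."""


class GeometryError(MangroveTypologyError, ValueError):
    """Invalid geometry that could not be repaired."""


class TopologyError(MangroveTypologyError, ValueError):
    """Broken network topology (e.g. dangling downstream pointer)."""


class UndefinedValueError(MangroveTypologyError, ValueError):
    """A statistic was requested over no valid data."""
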