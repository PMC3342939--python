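"""Exception types shared across the package."""


class FlysleepError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FlysleepError):
    """A monitor or table file could not be parsed."""


class OrderingError(FlysleepError):
    """Timestamps in a monitor file are duplicated or otherwise unusable."""


class QualityError(FlysleepError):
    """A recording fails a quality-control gate (e.g. too many missing minutes)."""


class DesignError(FlysleepError):
    """The experiment-design table is inconsistent (duplicate keys, missing controls)."""


class ConfigError(FlysleepError):
    """A run configuration is invalid."""
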