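"""Exception hierarchy.

Three broad families map onto distinct CLI exit codes: configuration
problems (caught before any data is touched), data-quality problems
(detected during a stage), and computational degeneracies (undefined
statistics on otherwise valid data).
"""


class MyocohError(Exception):
    """Base class for all package errors."""


class ConfigError(MyocohError):
    """Invalid or out-of-range configuration value."""


class ParameterError(ConfigError):
    """A single operation parameter is out of its admissible range."""


class MappingError(MyocohError):
    """A channel map references a label that does not exist."""


class IngestionError(MyocohError):
    """Unreadable, non-numeric or NaN-containing input data."""


class ScheduleError(MyocohError):
    """Trial schedule incompatible with the requested analysis window."""


class QualityError(MyocohError):
    """Data failed a quality gate (e.g. too many bad channels)."""


class MontageError(QualityError):
    """No usable electrode remains for a required hemisphere."""


class DegenerateError(MyocohError):
    """A statistic is undefined on this input (zero variance, zero sum)."""
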