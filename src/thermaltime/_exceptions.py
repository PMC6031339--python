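"""Exception hierarchy for the thermaltime package.

Everything raised deliberately by the library derives from
:class:`ThermalTimeError`, so callers (and the CLI) can distinguish
domain/validation failures from programming errors.
"""


class ThermalTimeError(Exception):
    """Base class for all thermaltime errors."""


class ConfigurationError(ThermalTimeError):
    """Invalid model or run configuration (e.g. t_ref <= t0)."""


class TraceValidationError(ThermalTimeError):
    """A temperature trace violates its invariants."""


class DegenerateDesignError(ThermalTimeError):
    """Rate data with fewer than two distinct temperatures."""


class NonPositiveSlopeError(ThermalTimeError):
    """Fitted rate-vs-temperature slope is not positive; no developmental
    zero exists within the model's range."""


class UnstableDesignError(ThermalTimeError):
    """Bootstrap resampling discarded more than half of its draws."""


class TraceTooShortError(ThermalTimeError):
    """A temperature trace ends before the thermal budget is reached."""


class TableFormatError(ThermalTimeError):
    """A CSV input file does not conform to its documented dialect."""
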