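"""Exception hierarchy for protocol scoring and agreement statistics.

Validation of field data is fail-open elsewhere (violations are collected);
these exceptions mark conditions under which a computation is genuinely
undefined or an input is structurally unusable.
"""


class WQAgreeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(WQAgreeError):
    """A record is missing required fields or references an unknown id."""


class RangeError(WQAgreeError):
    """A value lies outside its legal scale (e.g. a VAS mark beyond 125 mm)."""


class PairingError(WQAgreeError):
    """A farm visit lacks its second observer, or has too many records."""


class IntegrityError(WQAgreeError):
    """Conflicting duplicate records for the same (visit, observer)."""


class LayoutError(WQAgreeError):
    """A measure table is not a complete two-way (visits x observers) layout."""


class InsufficientDataError(WQAgreeError):
    """Fewer paired visits than the statistic requires (minimum 3)."""


class UndefinedStatisticError(WQAgreeError):
    """The statistic has no defined value for this input.

    Raised e.g. for a Spearman correlation of a constant vector, a
    prevalence over zero assessed animals, a behaviour fraction with no
    active observations, or an ICC when every variance component is zero.
    """


class ConfigError(WQAgreeError):
    """Invalid protocol definition, thresholds or simulation configuration."""
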