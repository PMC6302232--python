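"""Shared helpers: half-up rounding and error types."""

from decimal import ROUND_HALF_UP, Decimal


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the field."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Published percentage tables round 0.5 up (22.455 -> 22.46), which
    differs from Python's banker's rounding; all reported percentages
    and corrected counts go through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage rounded half-up; denominator must be nonzero."""
    return round_half_up(100.0 * numerator / denominator, ndigits)
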