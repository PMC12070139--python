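"""Half-up rounding matching how the report tables print proportions."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "pct"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.125 -> 0.13 at 2 digits),
    unlike builtin banker's rounding."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_up(100.0 * numerator / denominator, ndigits)
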