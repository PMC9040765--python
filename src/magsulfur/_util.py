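"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as printed report tables expect.

    Python's built-in ``round`` uses banker's rounding, which would turn
    e.g. 0.125 into 0.12; report percentages follow the half-up convention
    instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty collection is undefined")
    return round_half_up(100.0 * numerator / denominator, ndigits)
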