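"""Rounding helper for report tables."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(value: float, digits: int = 0) -> float:
    """Round half away from zero (the convention of printed agronomy tables,
    unlike Python's banker's rounding)."""
    q = Decimal(1).scaleb(-digits)
    d = Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)
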