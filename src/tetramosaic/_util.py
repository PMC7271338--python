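"""Small shared helpers."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching hand-reported precision.

    Python's built-in ``round`` uses banker's rounding (96.085 -> 96.08);
    field reports round half up (96.085 -> 96.09).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
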