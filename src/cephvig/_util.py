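"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as printed tables conventionally do.

    Python's built-in ``round`` uses banker's rounding; regulatory tables
    (and this package's rendered output) round 0.5 up instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
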