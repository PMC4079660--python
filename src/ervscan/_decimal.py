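"""Half-up decimal rounding, matching how percentages are conventionally
printed in tables (Python's round() is banker's rounding)."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
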