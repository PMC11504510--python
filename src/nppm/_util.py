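"""Small numeric helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float | int:
    """Round with ties away from zero (commercial rounding), not banker's.

    Reported proportions and deviations use half-up rounding so that exact
    halves such as 22.5 and 97.5 round to 23 and 98.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    rounded = Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(rounded) if ndigits > 0 else int(rounded)
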