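"""Half-up decimal rounding for the reporting layer.

All areas are carried at full float precision internally; rounding happens
only when numbers are printed or compared against published values, using
half-up ties (0.0285 → 0.029 at 3 dp) rather than the float default.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
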