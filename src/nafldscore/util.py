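"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves going away from zero (0.5 -> 1, -0.5 -> -1).

    Python's built-in ``round`` uses banker's rounding; reported frequencies,
    score means and integer point weights follow the lay convention instead.
    Goes through the shortest decimal repr so that values printed as exact
    halves round as such.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
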