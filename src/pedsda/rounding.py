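"""Half-up decimal rounding, matching the convention of printed tables."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero-half up.

    Python's built-in ``round`` is banker's rounding; published
    percentage tables round 0.05 up, so 19.65 -> 19.7.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
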