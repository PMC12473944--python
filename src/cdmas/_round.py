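"""Half-up decimal rounding, shared by display/summary code.

Python's built-in ``round`` is banker's rounding; printed agronomy tables
round half away from zero, so summaries that mimic them must too.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
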