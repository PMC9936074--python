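"""Shared numeric helpers.

Reported integers and percentages round half away from zero, matching how
run summaries in targeted-panel reports are conventionally printed
(e.g. 0.85028 -> 0.9 at one decimal).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float | int:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero.

    Returns an ``int`` when ``ndigits == 0``.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP)
    return int(d) if ndigits == 0 else float(d)


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """Percentage of ``count`` in ``total`` to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(round_half_away(100.0 * count / total, ndigits))


class ValidationError(ValueError):
    """Raised when an input record violates a documented invariant."""
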