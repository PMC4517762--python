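"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention used in all
    report-style outputs, where e.g. 74.75 -> 74.8).

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    how clinical tables are typeset.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(x: float, ndigits: int = 1) -> float:
    """Proportion -> percent, rounded half away from zero."""
    return round_half_away(100.0 * x, ndigits)
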