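"""Decimal rounding helpers.

The survey prints numbers under two conventions: summary statistics and
referral percentages are rounded half-up, while the error-rate
percentages in the nomenclature tally are truncated toward zero.  Both
are provided here so each stage can match its printed convention, and
both avoid binary-float surprises by going through ``decimal``.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP

__all__ = ["round_half_up", "truncate"]


def _quantum(ndigits: int) -> Decimal:
    return Decimal(1).scaleb(-ndigits)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties away from zero (0.035 -> 0.04)."""
    return float(Decimal(str(float(x))).quantize(_quantum(ndigits), rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 2) -> float:
    """Drop digits beyond ``ndigits`` without rounding (10.5263 -> 10.52)."""
    return float(Decimal(str(float(x))).quantize(_quantum(ndigits), rounding=ROUND_DOWN))
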