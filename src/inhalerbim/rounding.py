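"""Display rounding and number formatting.

All model arithmetic is carried at full floating-point precision; rounding
happens once, at display time. The conventions are round-half-up to the
nearest person or pound and two decimal places for percentages, matching
the usual presentation of budget-impact tables (e.g. 3 405 363.5 persons is
displayed as 3 405 364).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: Thin space used as the thousands separator in rendered tables.
THIN_SPACE = " "


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round ``value`` to ``decimals`` places, halves away from zero upward.

    Python's built-in ``round`` uses banker's rounding; financial tables use
    half-up. ``Decimal(repr(value))`` avoids binary representation fuzz so
    that e.g. 2.675 rounds on its printed value.
    """
    quantum = Decimal(1).scaleb(-decimals)
    # float() first: numpy scalars repr as "np.float64(...)"
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def display_persons(count: float) -> int:
    """Whole-person display value of an unrounded patient count."""
    return int(round_half_up(count, 0))


def display_currency(amount: float) -> int:
    """Nearest-pound display value of an unrounded cost."""
    return int(round_half_up(amount, 0))


def display_percent(pct: float) -> float:
    """Two-decimal display value of a percentage."""
    return round_half_up(pct, 2)


def group_thousands(value: int, sep: str = THIN_SPACE) -> str:
    """Format an integer with thin-space thousands grouping (``27 422``)."""
    return f"{value:,}".replace(",", sep)
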