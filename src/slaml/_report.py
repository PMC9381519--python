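"""Report-level rounding conventions.

Percentages are carried at full precision everywhere and rounded only for
display: half-away-from-zero, one decimal for percentages, two for relative
risks.
"""

from __future__ import annotations

import decimal
import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (not banker's rounding).

    Uses the shortest-repr decimal of ``x`` so that values like 97.555
    (stored as 97.55500000000001 or 97.55499999999999) round the way the
    printed number suggests.
    """
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return x
    d = decimal.Decimal(repr(float(x)))
    exp = decimal.Decimal(1).scaleb(-ndigits)
    return float(d.quantize(exp, rounding=decimal.ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100*numerator/denominator rounded per the report convention.

    Returns NaN for a zero denominator (undefined, never an exception).
    """
    if denominator == 0:
        return float("nan")
    return round_half_away(100.0 * numerator / denominator, ndigits)


def ratio(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Plain ratio (e.g. mice per sample) rounded to ``ndigits``."""
    if denominator == 0:
        return float("nan")
    return round_half_away(numerator / denominator, ndigits)
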