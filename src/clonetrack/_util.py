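"""Small shared helpers: display rounding and trend summaries."""

from __future__ import annotations

import math
from typing import Sequence

__all__ = ["round_half_away", "series_direction", "least_squares_slope"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of printed
    clinical tables, unlike banker's rounding of the builtin).

    A 1e-9 guard absorbs binary representation error just below a tie
    (e.g. 2.675 stored as 2.67499...).
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5 + 1e-9), x) / scale


def series_direction(values: Sequence[float]) -> str:
    """Classify an ordered series: 'n/a' (single point), 'stable',
    'non-decreasing', 'non-increasing' or 'mixed'."""
    if len(values) == 0:
        raise ValueError("empty series")
    if len(values) == 1:
        return "n/a"
    diffs = [b - a for a, b in zip(values, values[1:])]
    if all(d == 0 for d in diffs):
        return "stable"
    if all(d >= 0 for d in diffs):
        return "non-decreasing"
    if all(d <= 0 for d in diffs):
        return "non-increasing"
    return "mixed"


def least_squares_slope(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Ordinary least-squares slope of y on x; None when underdetermined."""
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2 or len(set(x)) < 2:
        return None
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    return sxy / sxx
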