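"""Reporting arithmetic: the rounded percentages and fold changes a summary
prints."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, digits: int = 0) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_proportion(numerator: int, denominator: int, digits: int = 0) -> float:
    """numerator/denominator as a percentage, rounded half-up to ``digits``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(numerator / denominator * 100.0, digits)


def summarize_change(mean_a: float, mean_b: float) -> tuple[float, float]:
    """(percent change from a to b rounded to integer, max/min fold change)."""
    if mean_a <= 0:
        raise ValueError("baseline mean must be positive")
    percent = round_half_up((mean_b - mean_a) / mean_a * 100.0, 0)
    if mean_b <= 0:
        raise ValueError("comparison mean must be positive")
    fold = max(mean_a, mean_b) / min(mean_a, mean_b)
    return percent, fold
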