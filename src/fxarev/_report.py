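"""Reporting helpers: half-up rounding at the package's printed precisions."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

__all__ = ["DerivedValue", "round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero to ``ndigits`` decimals (2.5 -> 3)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


class DerivedValue(NamedTuple):
    """A reported number at its printed precision plus the exact value."""

    value: float
    exact: float
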