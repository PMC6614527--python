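"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero for positive x.

    Published health-planning tables are typically produced with
    half-up rounding, not banker's rounding, so ``round()`` is not a
    drop-in replacement (``round(0.5) == 0``).
    """
    return int(math.floor(x + 0.5))


def round1(x: float) -> float:
    """Round to one decimal place, halves up (table-display convention)."""
    return math.floor(x * 10 + 0.5) / 10
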