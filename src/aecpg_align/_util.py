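"""Small numeric helpers: half-up rounding and level snapping.

Report rounding deliberately uses half-up (so 0.825 -> 0.83, 57.5 -> 58)
rather than banker's rounding, matching how the summary tables are
conventionally printed.  Snapping maps an average back onto the discrete
scoring alphabet {0, 0.5, 1}; exact midpoints (0.25, 0.75) snap upward.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

SCORE_LEVELS: tuple[float, ...] = (0.0, 0.5, 1.0)

_TIE_EPS = 1e-12


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round *x* to *ndigits* decimals with ties going away from zero-ward up."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def snap_to_levels(
    x: float, levels: Sequence[float] = SCORE_LEVELS, tie: str = "up"
) -> float:
    """Snap *x* to the nearest level; ties go to the larger ('up') or smaller
    ('down') level.

    Comparisons use a 1e-12 slack so that exact midpoints computed in binary
    floating point (0.25, 0.75) are recognised as ties.
    """
    if tie not in ("up", "down"):
        raise ValueError(f"tie must be 'up' or 'down', got {tie!r}")
    dists = [abs(float(x) - lv) for lv in levels]
    best = min(dists)
    candidates = [lv for lv, d in zip(levels, dists) if d <= best + _TIE_EPS]
    return max(candidates) if tie == "up" else min(candidates)
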