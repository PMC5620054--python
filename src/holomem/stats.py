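"""Small statistical helpers shared across stages.

One rounding convention is declared here and used everywhere an integer
percentage appears: round half away from zero, matching the whole-percent
columns of the published species table.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

from scipy import stats as _scipy_stats
from sklearn.metrics import adjusted_rand_score

from .errors import DataError


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def integer_percent(part: float, total: float) -> int:
    """Whole-number percentage, half away from zero; scale-free in (part, total)."""
    if total <= 0:
        raise DataError(f"percentage of non-positive total {total}")
    return round_half_away(100.0 * part / total)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Refuses fewer than three observations: a two-point rank correlation
    is always +/-1 and carries no information.
    """
    if len(x) != len(y):
        raise DataError("spearman: unequal vector lengths")
    if len(x) < 3:
        raise DataError("spearman: need at least 3 observations")
    rho, _ = _scipy_stats.spearmanr(x, y)
    return float(rho)


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand Index between two labelings of the same items."""
    if len(labels_a) != len(labels_b):
        raise DataError("ARI: unequal label vector lengths")
    return float(adjusted_rand_score(list(labels_a), list(labels_b)))
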