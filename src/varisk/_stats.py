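"""Small statistical helpers used across the analysis modules."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["dependent_proportions_ztest", "longest_run", "first_run_start"]


def dependent_proportions_ztest(x1: np.ndarray, x2: np.ndarray):
    """Normal-approximation test of two proportions measured on the same units.

    McNemar-style: uses only discordant pairs, z = (b - c) / sqrt(b + c).
    Returns (z, two-sided p).
    """
    x1 = np.asarray(x1, dtype=bool)
    x2 = np.asarray(x2, dtype=bool)
    b = int(np.sum(x1 & ~x2))
    c = int(np.sum(~x1 & x2))
    if b + c == 0:
        return 0.0, 1.0
    z = (b - c) / np.sqrt(b + c)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = cur = 0
    for m in np.asarray(mask, dtype=bool):
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def first_run_start(mask: np.ndarray, min_len: int) -> int | None:
    """Index of the first run of True values strictly longer than ``min_len``.

    Returns None when no qualifying run exists.
    """
    mask = np.asarray(mask, dtype=bool)
    cur = 0
    for i, m in enumerate(mask):
        cur = cur + 1 if m else 0
        if cur > min_len:
            return i - cur + 1
    return None
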