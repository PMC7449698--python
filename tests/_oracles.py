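"""Naive reference implementations used as independent oracles in tests.

These deliberately use simple per-base loops and stay independent of the
library code paths they check.
"""

from __future__ import annotations

import numpy as np


def naive_segments(depth: np.ndarray, min_depth: float, max_gap: int,
                   inclusive: bool = False) -> list[tuple[int, int]]:
    """O(N) per-base segmentation: threshold, runs, merge-by-gap."""
    marked = [
        (d >= min_depth if inclusive else d > min_depth) for d in depth
    ]
    runs = []
    i = 0
    n = len(marked)
    while i < n:
        if marked[i]:
            j = i
            while j < n and marked[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def naive_region_sum(plus: np.ndarray, minus: np.ndarray, start: int, end: int,
                     strand: str, scale: float = 1.0) -> float:
    total = 0.0
    for i in range(start, end):
        if strand == "+":
            total += plus[i]
        elif strand == "-":
            total += minus[i]
        else:
            total += plus[i] + minus[i]
    return total * scale


def naive_binned_row(depth: np.ndarray, pos: int, strand: str, upstream: int,
                     downstream: int, binsize: int, scale: float = 1.0) -> list[float]:
    """Per-bin means 5'->3' around an anchor, NaN for fully out-of-bounds bins."""
    nbins = (upstream + downstream) // binsize
    # genomic coordinates of each base of the window, walked 5'->3'
    if strand == "-":
        coords = list(range(pos + upstream, pos - downstream, -1))
    else:
        coords = list(range(pos - upstream, pos + downstream))
    row = []
    for b in range(nbins):
        vals = [depth[c] for c in coords[b * binsize:(b + 1) * binsize]
                if 0 <= c < len(depth)]
        row.append(float(np.mean(vals)) * scale if vals else float("nan"))
    return row


def rank_sum_pvalue_enumeration(a, b) -> float:
    """Exact two-sided rank-sum p-value by exhaustive enumeration of labelings."""
    from itertools import combinations

    pooled = sorted(list(a) + list(b))
    ranks = {v: r + 1 for r, v in enumerate(pooled)}  # tie-free inputs only
    n_a = len(a)
    observed = sum(ranks[v] for v in a)
    mean = n_a * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in combinations(pooled, n_a):
        stat = sum(ranks[v] for v in combo)
        if abs(stat - mean) >= abs(observed - mean):
            count += 1
        total += 1
    return count / total
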