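"""Vectorized interval arithmetic on sorted, disjoint interval sets.

Internal helper for origin classification, coverage and feature counting.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    ivs = sorted(intervals)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def complement_intervals(intervals: Iterable[Interval], length: int) -> List[Interval]:
    """Gaps of ``[0, length)`` not covered by the (merged) intervals."""
    out: List[Interval] = []
    pos = 0
    for s, e in merge_intervals(intervals):
        s, e = max(s, 0), min(e, length)
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


class DisjointIntervals:
    """Sorted disjoint intervals supporting vectorized overlap queries."""

    def __init__(self, intervals: Iterable[Interval]):
        merged = merge_intervals(intervals)
        self.starts = np.array([s for s, _ in merged], dtype=np.int64)
        self.ends = np.array([e for _, e in merged], dtype=np.int64)

    def overlaps(self, q_starts: np.ndarray, q_ends: np.ndarray) -> np.ndarray:
        """Boolean array: does each query interval share >= 1 base?"""
        q_starts = np.asarray(q_starts, dtype=np.int64)
        q_ends = np.asarray(q_ends, dtype=np.int64)
        if self.starts.size == 0:
            return np.zeros(q_starts.shape, dtype=bool)
        # candidate: the last interval starting before the query end
        idx = np.searchsorted(self.starts, q_ends, side="left") - 1
        idx_clip = np.clip(idx, 0, self.starts.size - 1)
        return (idx >= 0) & (self.ends[idx_clip] > q_starts)
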