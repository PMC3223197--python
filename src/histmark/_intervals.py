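"""Set algebra on plain (start, end) interval lists, plus a fast tag index.

These helpers operate on bare integer pairs (half-open) within a single
chromosome; callers handle the per-chromosome bookkeeping.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .core import Tag

Span = Tuple[int, int]


def merge_spans(spans: Iterable[Span]) -> List[Span]:
    """Merge overlapping or touching half-open spans; result is sorted."""
    out: List[Span] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_spans(a: Sequence[Span], b: Sequence[Span]) -> List[Span]:
    """a minus b; both must be merged+sorted, result is merged+sorted."""
    out: List[Span] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def complement_spans(a: Sequence[Span], length: int) -> List[Span]:
    """Complement of merged+sorted spans within [0, length)."""
    return subtract_spans([(0, length)], list(a))


def intersect_len(a: Sequence[Span], span: Span) -> int:
    """Total overlap (bp) between merged spans `a` and a single span."""
    s, e = span
    total = 0
    for as_, ae in a:
        if as_ >= e:
            break
        total += max(0, min(ae, e) - max(as_, s))
    return total


class TagIndex:
    """Per-chromosome sorted arrays of tag starts/ends for O(log n) counting.

    A tag overlaps window [s, e) iff tag.start < e and tag.end > s, so the
    overlap count is (#starts < e) - (#ends <= s).
    """

    def __init__(self, tags: Iterable[Tag]):
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for t in tags:
            by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            self._starts[chrom] = np.sort(arr[:, 0])
            self._ends[chrom] = np.sort(arr[:, 1])

    def count(self, chrom: str, start: int, end: int) -> int:
        starts = self._starts.get(chrom)
        if starts is None:
            return 0
        ends = self._ends[chrom]
        return int(
            np.searchsorted(starts, end, side="left")
            - np.searchsorted(ends, start, side="right")
        )

    def count_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        s = self._starts.get(chrom)
        if s is None:
            return np.zeros(len(starts), dtype=np.int64)
        e = self._ends[chrom]
        return np.searchsorted(s, ends, side="left") - np.searchsorted(
            e, starts, side="right"
        )
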