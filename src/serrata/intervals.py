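"""Minimal interval-set arithmetic for callable regions (BED dialect).

Intervals are 0-based half-open ``(chrom, start, end)`` triples. The
operations here (merge, intersect, total length, membership) are the only
ones the pipeline needs, so we keep them dependency-free.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from typing import Iterable, Iterator

Interval = tuple[str, int, int]


class IntervalSet:
    """Immutable merged set of genomic intervals."""

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for chrom, start, end in intervals:
            if end < start:
                raise ValueError(f"interval end {end} < start {start} on {chrom}")
            if end > start:
                by_chrom[chrom].append((start, end))
        self._data: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._data[chrom] = merged
        # sorted starts per chrom for O(log n) membership
        self._starts = {c: [s for s, _ in ivs] for c, ivs in self._data.items()}

    def __iter__(self) -> Iterator[Interval]:
        for chrom in sorted(self._data):
            for s, e in self._data[chrom]:
                yield (chrom, s, e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())

    def __bool__(self) -> bool:
        return bool(self._data)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self._data == other._data

    def total_length(self) -> int:
        return sum(e - s for ivs in self._data.values() for s, e in ivs)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        ivs = self._data.get(chrom)
        if not ivs:
            return False
        i = bisect_right(self._starts[chrom], pos0) - 1
        return i >= 0 and ivs[i][0] <= pos0 < ivs[i][1]

    def contains_vcf_pos(self, chrom: str, pos1: int) -> bool:
        """Membership of a 1-based (VCF) position."""
        return self.contains(chrom, pos1 - 1)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: list[Interval] = []
        for chrom, ivs in self._data.items():
            theirs = other._data.get(chrom)
            if not theirs:
                continue
            i = j = 0
            while i < len(ivs) and j < len(theirs):
                s = max(ivs[i][0], theirs[j][0])
                e = min(ivs[i][1], theirs[j][1])
                if s < e:
                    out.append((chrom, s, e))
                if ivs[i][1] <= theirs[j][1]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out)
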