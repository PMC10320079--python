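"""Genomic intervals and merged interval sets.

All coordinates in this package are 0-based, half-open. Conversion to and
from 1-based file formats (GTF, VCF) happens only in :mod:`splicecall.formats`.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Tuple


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _merge_sorted(pairs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping or abutting sorted (start, end) pairs."""
    merged: List[Tuple[int, int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


class IntervalSet:
    """A set of genomic positions stored as merged, sorted intervals.

    The set is closed under merge: no two intervals on one chromosome
    overlap or abut. Strand is not tracked at the set level (region sets
    used for stratification and coverage are strandless).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            self._by_chrom[chrom] = _merge_sorted(pairs)

    @classmethod
    def _from_merged(cls, by_chrom: Dict[str, List[Tuple[int, int]]]) -> "IntervalSet":
        out = cls.__new__(cls)
        out._by_chrom = {c: list(p) for c, p in by_chrom.items() if p}
        return out

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._by_chrom):
            for s, e in self._by_chrom[chrom]:
                yield GenomicInterval(chrom, s, e)

    def __len__(self) -> int:
        return sum(len(p) for p in self._by_chrom.values())

    def __bool__(self) -> bool:
        return any(self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    def chroms(self) -> List[str]:
        return sorted(self._by_chrom)

    def pairs(self, chrom: str) -> List[Tuple[int, int]]:
        return list(self._by_chrom.get(chrom, []))

    def total_length(self) -> int:
        return sum(e - s for p in self._by_chrom.values() for s, e in p)

    def contains(self, chrom: str, pos: int) -> bool:
        """True if position ``pos`` (0-based) lies inside the set."""
        pairs = self._by_chrom.get(chrom)
        if not pairs:
            return False
        i = bisect_right(pairs, (pos, float("inf"))) - 1
        return i >= 0 and pairs[i][0] <= pos < pairs[i][1]

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, List[Tuple[int, int]]] = {}
        for chrom in self._by_chrom:
            a, b = self._by_chrom[chrom], other._by_chrom.get(chrom, [])
            i = j = 0
            res: List[Tuple[int, int]] = []
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    res.append((s, e))
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
            if res:
                out[chrom] = res
        return IntervalSet._from_merged(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other))

    def pad(self, padding: int, chrom_lengths: Dict[str, int] | None = None) -> "IntervalSet":
        """Extend every interval by ``padding`` on both sides and re-merge."""
        ivs = []
        for iv in self:
            s = max(0, iv.start - padding)
            e = iv.end + padding
            if chrom_lengths is not None and iv.chrom in chrom_lengths:
                e = min(e, chrom_lengths[iv.chrom])
            ivs.append(GenomicInterval(iv.chrom, s, e))
        return IntervalSet(ivs)
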