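"""Pileup construction and candidate variant discovery.

A candidate SNP needs at least ``min_alt_count`` (default 2) reads carrying
the same non-reference base, and at least ``min_alt_fraction`` of the
column depth — RNA coverage can run to thousands-fold, where two reads are
noise. Insertions and deletions are tallied at their left anchor column in
VCF convention (one reference anchor base, left-aligned).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .read_prep import ReadSegment

# allele keys inside a pileup column:
#   ("SNP", base)  ("INS", inserted_seq)  ("DEL", deleted_len)
AlleleKey = Tuple[str, object]


@dataclass
class AlleleObs:
    allele: AlleleKey
    count: int
    mean_base_qual: float
    forward: int
    reverse: int


@dataclass
class PileupColumn:
    chrom: str
    pos: int
    ref_base: str
    depth: int                      # reads with aligned base or deletion here
    alleles: List[AlleleObs]

    def obs(self, key: AlleleKey) -> Optional[AlleleObs]:
        for a in self.alleles:
            if a.allele == key:
                return a
        return None


@dataclass
class CandidateSite:
    """A putative variant: position, VCF-style alleles, and support."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: List[str]
    support: List[int]              # per alt
    depth: int
    kind: str                       # SNP | INS | DEL

    @property
    def alt_fraction(self) -> float:
        return self.support[0] / self.depth if self.depth else 0.0


def build_pileup(
    segments: Iterable[ReadSegment],
    chrom: str,
    start: int,
    end: int,
    reference: str,
    min_base_qual: int = 10,
) -> List[PileupColumn]:
    """Tally per-column allele observations over ``[start, end)``.

    Bases below ``min_base_qual`` count toward depth but not toward allele
    support. Insertions are anchored at the column of the preceding aligned
    base; deletions contribute a deletion allele at their anchor and depth
    at every deleted position. ``reference`` is the full chromosome
    sequence. Segments must be N-free.
    """
    if start < 0 or end > len(reference):
        raise ValueError(
            f"region {chrom}:{start}-{end} outside reference (len {len(reference)})"
        )
    depth: Counter = Counter()
    counts: Dict[int, Counter] = defaultdict(Counter)
    qual_sums: Dict[int, Counter] = defaultdict(Counter)
    fwd: Dict[int, Counter] = defaultdict(Counter)

    for seg in segments:
        if seg.chrom != chrom:
            continue
        rpos, qpos = seg.pos, 0
        for op, ln in seg.cigar:
            if op == "N":
                raise ValueError(f"segment {seg.name} contains N; split it first")
            if op in ("M", "=", "X"):
                lo = max(rpos, start)
                hi = min(rpos + ln, end)
                for p in range(lo, hi):
                    q = qpos + (p - rpos)
                    depth[p] += 1
                    if seg.base_quals[q] >= min_base_qual:
                        key = ("SNP", seg.seq[q])
                        counts[p][key] += 1
                        qual_sums[p][key] += seg.base_quals[q]
                        if not seg.is_reverse:
                            fwd[p][key] += 1
                rpos += ln
                qpos += ln
            elif op == "I":
                anchor = rpos - 1
                if start <= anchor < end and qpos > 0:
                    key = ("INS", seg.seq[qpos : qpos + ln])
                    counts[anchor][key] += 1
                    qual_sums[anchor][key] += seg.base_quals[qpos - 1]
                    if not seg.is_reverse:
                        fwd[anchor][key] += 1
                qpos += ln
            elif op == "D":
                anchor = rpos - 1
                if start <= anchor < end:
                    key = ("DEL", ln)
                    counts[anchor][key] += 1
                    if qpos > 0:
                        qual_sums[anchor][key] += seg.base_quals[qpos - 1]
                    if not seg.is_reverse:
                        fwd[anchor][key] += 1
                for p in range(max(rpos, start), min(rpos + ln, end)):
                    depth[p] += 1
                rpos += ln
            elif op in ("S", "H", "P"):
                if op == "S":
                    qpos += ln
            else:
                raise ValueError(f"unsupported CIGAR op {op}")

    columns: List[PileupColumn] = []
    for pos in sorted(set(depth) | set(counts)):
        obs = [
            AlleleObs(
                allele=key,
                count=n,
                mean_base_qual=qual_sums[pos][key] / n if n else 0.0,
                forward=fwd[pos][key],
                reverse=n - fwd[pos][key],
            )
            for key, n in sorted(
                counts[pos].items(), key=lambda kv: (-kv[1], str(kv[0]))
            )
        ]
        columns.append(
            PileupColumn(
                chrom=chrom,
                pos=pos,
                ref_base=reference[pos],
                depth=depth[pos],
                alleles=obs,
            )
        )
    return columns


def find_candidates(
    columns: Sequence[PileupColumn],
    reference: str,
    min_alt_count: int = 2,
    min_alt_fraction: float = 0.1,
) -> List[CandidateSite]:
    """Propose candidate sites from pileup columns.

    An alternate allele is kept iff its count >= ``min_alt_count`` and its
    fraction of column depth >= ``min_alt_fraction``. At most two alts are
    retained per site and kind, by descending count with lexicographic
    tie-break. SNP and indel candidates at one position are reported as
    separate sites.
    """
    out: List[CandidateSite] = []
    for col in columns:
        if col.depth == 0:
            continue
        kept: Dict[str, List[Tuple[int, str, str]]] = {"SNP": [], "INS": [], "DEL": []}
        for obs in col.alleles:
            kind, val = obs.allele
            if obs.count < min_alt_count or obs.count / col.depth < min_alt_fraction:
                continue
            if kind == "SNP":
                if val == col.ref_base:
                    continue
                ref, alt = col.ref_base, str(val)
            elif kind == "INS":
                ref, alt = col.ref_base, col.ref_base + str(val)
            else:  # DEL
                dlen = int(val)  # type: ignore[arg-type]
                if col.pos + 1 + dlen > len(reference):
                    continue
                ref = reference[col.pos : col.pos + 1 + dlen]
                alt = col.ref_base
            kept[kind].append((obs.count, alt, ref))
        for kind, alts in kept.items():
            if not alts:
                continue
            alts.sort(key=lambda t: (-t[0], t[1]))
            # deletions of different lengths need different REF alleles;
            # keep only the best-supported one per site
            alts = alts[:1] if kind == "DEL" else alts[:2]
            out.append(
                CandidateSite(
                    chrom=col.chrom,
                    pos=col.pos,
                    ref_allele=alts[0][2],
                    alt_alleles=[a for _, a, _ in alts],
                    support=[c for c, _, _ in alts],
                    depth=col.depth,
                    kind=kind,
                )
            )
    return out


def scan_region(
    segments: Iterable[ReadSegment],
    chrom: str,
    start: int,
    end: int,
    reference: str,
    min_base_qual: int = 10,
    min_alt_count: int = 2,
    min_alt_fraction: float = 0.1,
) -> List[CandidateSite]:
    cols = build_pileup(segments, chrom, start, end, reference, min_base_qual)
    return find_candidates(cols, reference, min_alt_count, min_alt_fraction)
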