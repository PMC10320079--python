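"""Read filtering and splitting of spliced reads at SKIP (N) CIGAR ops.

Spliced aligners encode introns as N operations. Downstream pileup and
example encoding work on intron-free segments, so each read is cut into
one segment per maximal N-free CIGAR run. Query bases and qualities are
partitioned without loss; each segment remembers its parent read and index.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam

log = logging.getLogger(__name__)

QUERY_OPS = set("MIS=X")
REF_OPS = set("MDN=X")


@dataclass
class AlignedRead:
    """An aligned read: position, CIGAR, bases, qualities, flags."""

    name: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    cigar: List[Tuple[str, int]]
    seq: str
    base_quals: List[int]
    mapq: int = 60
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_unmapped: bool = False
    is_reverse: bool = False

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
        if qlen != len(self.seq) or len(self.seq) != len(self.base_quals):
            raise ValueError(
                f"read {self.name}: CIGAR query length {qlen} != "
                f"seq {len(self.seq)} / quals {len(self.base_quals)}"
            )

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in REF_OPS)


@dataclass
class ReadSegment(AlignedRead):
    """An N-free piece of a split read."""

    parent_name: str = ""
    segment_index: int = 0


_OP_CHARS = "MIDNSHP=X"


def from_pysam(a: pysam.AlignedSegment) -> AlignedRead:
    quals = list(a.query_qualities) if a.query_qualities is not None else [0] * len(a.query_sequence or "")
    return AlignedRead(
        name=a.query_name,
        chrom=a.reference_name if not a.is_unmapped else "*",
        pos=a.reference_start if not a.is_unmapped else -1,
        cigar=[(_OP_CHARS[op], ln) for op, ln in (a.cigartuples or [])],
        seq=a.query_sequence or "",
        base_quals=quals,
        mapq=a.mapping_quality,
        is_duplicate=a.is_duplicate,
        is_secondary=a.is_secondary,
        is_supplementary=a.is_supplementary,
        is_unmapped=a.is_unmapped,
        is_reverse=a.is_reverse,
    )


def filter_reads(
    reads: Iterable[AlignedRead], min_mapq: int = 1
) -> Tuple[List[AlignedRead], Counter]:
    """Drop unmapped/secondary/supplementary/duplicate and low-MAPQ reads.

    Returns (kept_reads, counts_removed_by_reason).
    """
    kept: List[AlignedRead] = []
    removed: Counter = Counter()
    for r in reads:
        if r.is_unmapped:
            removed["unmapped"] += 1
        elif r.is_secondary:
            removed["secondary"] += 1
        elif r.is_supplementary:
            removed["supplementary"] += 1
        elif r.is_duplicate:
            removed["duplicate"] += 1
        elif r.mapq < min_mapq:
            removed["low_mapq"] += 1
        else:
            kept.append(r)
    if removed:
        log.info("filter_reads removed: %s", dict(removed))
    return kept, removed


def split_skip_reads(
    read: AlignedRead, min_segment_len: int = 15
) -> List[ReadSegment]:
    """Split one read into N-free segments.

    Segment k starts at the parent position plus the reference length
    consumed by all prior ops including skipped introns. Segments with
    fewer than ``min_segment_len`` aligned query bases are dropped (tiny
    exon overhangs carry no usable variant context). A read without N ops
    comes back as a single segment identical to the input. A CIGAR that
    begins or ends with N is a malformed alignment.
    """
    if not read.cigar:
        return []
    if read.cigar[0][0] == "N" or read.cigar[-1][0] == "N":
        raise ValueError(f"read {read.name}: CIGAR begins or ends with N")

    runs: List[Tuple[int, List[Tuple[str, int]], int]] = []  # (ref_start, ops, q_start)
    ref_pos = read.pos
    q_pos = 0
    cur_ops: List[Tuple[str, int]] = []
    cur_ref_start = read.pos
    cur_q_start = 0
    for op, ln in read.cigar:
        if op == "N":
            if cur_ops:
                runs.append((cur_ref_start, cur_ops, cur_q_start))
            ref_pos += ln
            cur_ops = []
            cur_ref_start = ref_pos
            cur_q_start = q_pos
        else:
            cur_ops.append((op, ln))
            if op in REF_OPS:
                ref_pos += ln
            if op in QUERY_OPS:
                q_pos += ln
    if cur_ops:
        runs.append((cur_ref_start, cur_ops, cur_q_start))

    segments: List[ReadSegment] = []
    dropped = 0
    for idx, (ref_start, ops, q_start) in enumerate(runs):
        q_len = sum(n for op, n in ops if op in QUERY_OPS)
        aligned = sum(n for op, n in ops if op in ("M", "=", "X"))
        seg = ReadSegment(
            name=f"{read.name}/{idx}" if len(runs) > 1 else read.name,
            chrom=read.chrom,
            pos=ref_start,
            cigar=list(ops),
            seq=read.seq[q_start : q_start + q_len],
            base_quals=read.base_quals[q_start : q_start + q_len],
            mapq=read.mapq,
            is_duplicate=read.is_duplicate,
            is_reverse=read.is_reverse,
            parent_name=read.name,
            segment_index=idx,
        )
        if len(runs) > 1 and aligned < min_segment_len:
            dropped += 1
            continue
        segments.append(seg)
    if dropped:
        log.debug("split_skip_reads: dropped %d short segments of %s", dropped, read.name)
    return segments


def split_all(
    reads: Iterable[AlignedRead], min_segment_len: int = 15
) -> List[ReadSegment]:
    out: List[ReadSegment] = []
    for r in reads:
        out.extend(split_skip_reads(r, min_segment_len=min_segment_len))
    return out


def load_segments(
    bam_path: str,
    chrom: Optional[str] = None,
    min_mapq: int = 1,
    min_segment_len: int = 15,
) -> List[ReadSegment]:
    """Read a BAM, filter, and split into N-free segments."""
    with pysam.AlignmentFile(bam_path) as bam:
        it = bam.fetch(chrom) if chrom is not None else bam.fetch()
        reads = [from_pysam(a) for a in it]
    kept, _ = filter_reads(reads, min_mapq=min_mapq)
    return split_all(kept, min_segment_len=min_segment_len)


def write_segments_bam(
    segments: Sequence[ReadSegment], contigs, path: str
) -> None:
    """Write segments as a coordinate-sorted BAM with parent-name (ZP) and
    segment-index (ZS) tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in sorted(contigs.items())],
    }
    tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    code = {c: i for i, c in enumerate(_OP_CHARS)}
    ordered = sorted(segments, key=lambda s: (s.chrom, s.pos, s.name))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for s in ordered:
            a = pysam.AlignedSegment()
            a.query_name = s.name
            a.reference_id = tid[s.chrom]
            a.reference_start = s.pos
            a.mapping_quality = s.mapq
            a.cigartuples = [(code[op], ln) for op, ln in s.cigar]
            a.query_sequence = s.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in s.base_quals)
            )
            a.flag = (0x10 if s.is_reverse else 0) | (0x400 if s.is_duplicate else 0)
            a.set_tag("ZP", s.parent_name)
            a.set_tag("ZS", s.segment_index)
            bam.write(a)
    pysam.index(path)
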