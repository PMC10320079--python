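"""Channel-encoded pileup examples — the classifier's input.

Each candidate (and each of its alternate alleles) becomes a fixed-shape
tensor of height H (reference row + up to H-1 read rows), width W (an odd
window centred on the candidate) and 6 channels:

  0. base identity: A=0.25, C=0.50, G=0.75, T=1.00; gap/other and pad = 0
  1. base quality:  min(q, cap) / cap
  2. mapping quality: min(mapq, cap) / cap
  3. strand: forward 1.0, reverse 0.5, pad 0
  4. supports-alt: 1.0 if the read carries the scored alt at the candidate,
     0.5 otherwise, pad 0 (painted across the read's covered columns)
  5. differs-from-ref: 1.0 where the read base mismatches the reference

Row 0 holds the reference track (base identity; quality/mapq channels at
their maximum). All values lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .candidates import CandidateSite
from .formats import VariantRecord
from .intervals import IntervalSet
from .read_prep import ReadSegment

BASE_VALUES = {"A": 0.25, "C": 0.50, "G": 0.75, "T": 1.00}
N_CHANNELS = 6


@dataclass
class EncoderConfig:
    width: int = 221           # odd, candidate column central
    height: int = 101          # reference row + up to height-1 read rows
    base_qual_cap: int = 40
    mapq_cap: int = 60
    seed: int = 0              # read downsampling when rows exceed height-1

    def __post_init__(self) -> None:
        if self.width % 2 != 1:
            raise ValueError("width must be odd so the candidate column is central")
        if self.height < 2:
            raise ValueError("height must be >= 2")

    @property
    def center(self) -> int:
        return (self.width - 1) // 2


@dataclass
class PileupExample:
    candidate: CandidateSite
    alt_index: int
    tensor: np.ndarray         # (H, W, 6) float32 in [0, 1]
    label: Optional[int] = None  # 0 hom-ref, 1 het, 2 hom-alt


def _segment_covers(seg: ReadSegment, pos: int) -> bool:
    return seg.pos <= pos < seg.reference_end


def read_supports_alt(seg: ReadSegment, candidate: CandidateSite, alt: str) -> bool:
    """Does this segment carry the scored alternate allele at the candidate?

    SNP: aligned base at the candidate position equals the alt base.
    INS: the segment has an insertion of exactly the alt's inserted bases
    anchored at the candidate position. DEL: a deletion of the right length
    anchored there.
    """
    rpos, qpos = seg.pos, 0
    want = None
    if candidate.kind == "SNP":
        want = ("SNP", alt)
    elif candidate.kind == "INS":
        want = ("INS", alt[1:])
    else:
        want = ("DEL", len(candidate.ref_allele) - 1)
    for op, ln in seg.cigar:
        if op in ("M", "=", "X"):
            if want[0] == "SNP" and rpos <= candidate.pos < rpos + ln:
                return seg.seq[qpos + candidate.pos - rpos] == want[1]
            rpos += ln
            qpos += ln
        elif op == "I":
            if want[0] == "INS" and rpos - 1 == candidate.pos:
                return seg.seq[qpos : qpos + ln] == want[1]
            qpos += ln
        elif op == "D":
            if want[0] == "DEL" and rpos - 1 == candidate.pos:
                return ln == want[1]
            rpos += ln
        elif op == "S":
            qpos += ln
    return False


def encode_example(
    candidate: CandidateSite,
    alt_index: int,
    segments: Sequence[ReadSegment],
    reference: str,
    config: EncoderConfig,
) -> PileupExample:
    """Encode one (candidate, alt) into the fixed-shape tensor.

    Reads are sorted by (start, name); if more than height-1 overlap the
    window they are downsampled uniformly with the config seed. A candidate
    with no overlapping segment yields an all-pad pileup below the
    reference row (not an error).
    """
    H, W = config.height, config.width
    c = config.center
    win_start = candidate.pos - c
    alt = candidate.alt_alleles[alt_index]
    t = np.zeros((H, W, N_CHANNELS), dtype=np.float32)

    # reference row
    for j in range(W):
        p = win_start + j
        if 0 <= p < len(reference):
            t[0, j, 0] = BASE_VALUES.get(reference[p], 0.0)
            t[0, j, 1] = 1.0
            t[0, j, 2] = 1.0

    overlapping = [
        s for s in segments
        if s.chrom == candidate.chrom
        and s.pos < win_start + W
        and s.reference_end > win_start
        and _segment_covers(s, candidate.pos)
    ]
    overlapping.sort(key=lambda s: (s.pos, s.name))
    if len(overlapping) > H - 1:
        rng = np.random.default_rng(config.seed)
        idx = np.sort(rng.choice(len(overlapping), size=H - 1, replace=False))
        overlapping = [overlapping[i] for i in idx]

    for row, seg in enumerate(overlapping, start=1):
        supports = read_supports_alt(seg, candidate, alt)
        strand_val = 0.5 if seg.is_reverse else 1.0
        support_val = 1.0 if supports else 0.5
        mapq_val = min(seg.mapq, config.mapq_cap) / config.mapq_cap
        rpos, qpos = seg.pos, 0
        for op, ln in seg.cigar:
            if op in ("M", "=", "X"):
                lo = max(rpos, win_start)
                hi = min(rpos + ln, win_start + W)
                for p in range(lo, hi):
                    q = qpos + (p - rpos)
                    j = p - win_start
                    base = seg.seq[q]
                    t[row, j, 0] = BASE_VALUES.get(base, 0.0)
                    t[row, j, 1] = min(seg.base_quals[q], config.base_qual_cap) / config.base_qual_cap
                    t[row, j, 2] = mapq_val
                    t[row, j, 3] = strand_val
                    t[row, j, 4] = support_val
                    if 0 <= p < len(reference) and base != reference[p]:
                        t[row, j, 5] = 1.0
                rpos += ln
                qpos += ln
            elif op == "I":
                qpos += ln
            elif op == "D":
                lo = max(rpos, win_start)
                hi = min(rpos + ln, win_start + W)
                for p in range(lo, hi):
                    j = p - win_start
                    t[row, j, 1] = min(30, config.base_qual_cap) / config.base_qual_cap
                    t[row, j, 2] = mapq_val
                    t[row, j, 3] = strand_val
                    t[row, j, 4] = support_val
                    t[row, j, 5] = 1.0
                rpos += ln
            elif op == "S":
                qpos += ln
    return PileupExample(candidate=candidate, alt_index=alt_index, tensor=t)


# ---------------------------------------------------------------------------
# Silver-truth labelling


def _truth_label(candidate: CandidateSite, alt: str,
                 truth_var: Optional[VariantRecord]) -> int:
    """Map a truth genotype onto the 3 classes for the scored alt."""
    if truth_var is None or truth_var.genotype is None:
        return 0
    alleles = [truth_var.ref_allele] + list(truth_var.alt_alleles)
    gt_seqs = [alleles[i] for i in truth_var.genotype]
    n_alt = sum(1 for a in gt_seqs if a == alt)
    if truth_var.ref_allele != candidate.ref_allele:
        return 0
    return {0: 0, 1: 1, 2: 2}[n_alt]


def make_labeled_examples(
    candidates: Sequence[CandidateSite],
    truth_variants: Sequence[VariantRecord],
    segments: Sequence[ReadSegment],
    reference_by_chrom: Dict[str, str],
    config: EncoderConfig,
    confident_regions: IntervalSet,
) -> List[PileupExample]:
    """Encode candidates and attach silver-truth labels.

    A candidate matching a truth variant (same chrom/pos and alleles after
    normalization) is labelled by the truth genotype with respect to the
    scored alt. A candidate inside the confident regions with no truth
    match is labelled homozygous-reference; candidates outside the
    confident regions are excluded.
    """
    for v in truth_variants:
        if v.genotype is None:
            raise ValueError(
                f"truth variant {v.chrom}:{v.pos} lacks a genotype; "
                "labels require genotyped truth"
            )
    truth_by_site = {(v.chrom, v.pos): v for v in truth_variants}
    out: List[PileupExample] = []
    for cand in candidates:
        if not confident_regions.contains(cand.chrom, cand.pos):
            continue
        tv = truth_by_site.get((cand.chrom, cand.pos))
        for ai, alt in enumerate(cand.alt_alleles):
            ex = encode_example(
                cand, ai, segments, reference_by_chrom[cand.chrom], config
            )
            ex.label = _truth_label(cand, alt, tv)
            out.append(ex)
    return out
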