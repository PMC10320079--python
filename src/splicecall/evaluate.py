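"""Genotype-level benchmarking against a truth VCF.

Matching is normalized genotype concordance: a call is a true positive iff
a truth record exists at the same chromosome/position with identical
alleles (after left-aligned minimal representation) and the same unordered
genotype. A genotype mismatch at matching alleles counts as one false
positive and one false negative. This is deliberately simpler than
haplotype-resolved matching engines; it is exact on simulator output,
which emits normalized truth.

Stratifications mirror standard practice for transcriptome variant
calling: region class (CDS/exon/transcript/gene), minimum-coverage BED,
held-out chromosome, and signed distance to the nearest exon boundary.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .formats import VariantRecord, is_normalized
from .intervals import GenomicInterval, IntervalSet


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    stratum: str = "all"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)

    @property
    def fdr(self) -> Optional[float]:
        p = self.precision
        return None if p is None else 1.0 - p


def precision_recall_f1(tp: int, fp: int, fn: int):
    """(precision, recall, f1); entries are None on a zero denominator."""
    r = EvalResult(tp, fp, fn)
    return r.precision, r.recall, r.f1


# ---------------------------------------------------------------------------
# Coverage


def coverage_regions(
    bam_path: str,
    min_depth: int = 3,
    min_mapq: int = 1,
    chroms: Optional[Sequence[str]] = None,
) -> IntervalSet:
    """Maximal intervals where filtered-read depth >= ``min_depth``.

    Depth is computed after the caller's read filters (duplicates,
    secondary/supplementary, MAPQ), so evaluation coverage matches what the
    caller could actually see. ``min_depth=0`` returns whole contigs.
    """
    ivs: List[GenomicInterval] = []
    with pysam.AlignmentFile(bam_path) as bam:
        targets = list(chroms) if chroms is not None else list(bam.references)
        for chrom in targets:
            length = bam.get_reference_length(chrom)
            if min_depth == 0:
                ivs.append(GenomicInterval(chrom, 0, length))
                continue
            depth = np.zeros(length, dtype=np.int32)
            for a in bam.fetch(chrom):
                if (a.is_unmapped or a.is_secondary or a.is_supplementary
                        or a.is_duplicate or a.mapping_quality < min_mapq):
                    continue
                for s, e in a.get_blocks():
                    depth[s:e] += 1
            above = depth >= min_depth
            if not above.any():
                continue
            edges = np.flatnonzero(np.diff(above.astype(np.int8)))
            starts = [0] if above[0] else []
            starts += [int(i) + 1 for i in edges if not above[i]]
            ends = [int(i) + 1 for i in edges if above[i]]
            if above[-1]:
                ends.append(length)
            for s, e in zip(starts, ends):
                ivs.append(GenomicInterval(chrom, s, e))
    return IntervalSet(ivs)


# ---------------------------------------------------------------------------
# Concordance


def _kind(rec: VariantRecord) -> str:
    return "SNP" if rec.is_snp else "INDEL"


def _check_normalized(rec: VariantRecord) -> None:
    for alt in rec.alt_alleles:
        if not is_normalized(rec.ref_allele, alt):
            raise ValueError(
                f"un-normalized record {rec.chrom}:{rec.pos} "
                f"{rec.ref_allele}>{alt}; left-align and trim first"
            )


@dataclass
class Outcome:
    """One classified record for downstream profiling (editing, boundary)."""

    outcome: str                    # TP | FP | FN
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str


def compare_calls(
    calls: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    regions: Optional[IntervalSet] = None,
    variant_kind: str = "SNP",
) -> Tuple[EvalResult, List[Outcome]]:
    """Genotype concordance of calls against truth within ``regions``.

    Returns the counts plus per-record outcomes. Homozygous-reference and
    no-genotype calls are ignored; records outside ``regions`` are ignored;
    only records of ``variant_kind`` (SNP or INDEL) are considered.
    """

    def eligible(rec: VariantRecord) -> bool:
        if _kind(rec) != variant_kind:
            return False
        if regions is not None and not regions.contains(rec.chrom, rec.pos):
            return False
        return True

    def is_variant_call(rec: VariantRecord) -> bool:
        return rec.genotype is not None and any(i > 0 for i in rec.genotype)

    calls_use = [r for r in calls if eligible(r) and is_variant_call(r)]
    truth_use = [r for r in truth if eligible(r) and is_variant_call(r)]
    for rec in calls_use + truth_use:
        _check_normalized(rec)

    truth_by_site: Dict[Tuple[str, int], List[VariantRecord]] = defaultdict(list)
    for t in truth_use:
        truth_by_site[(t.chrom, t.pos)].append(t)

    tp = fp = fn = 0
    outcomes: List[Outcome] = []
    matched_truth: set = set()
    for c in calls_use:
        site_truth = truth_by_site.get((c.chrom, c.pos), [])
        hit = None
        for t in site_truth:
            if id(t) in matched_truth:
                continue
            if t.ref_allele == c.ref_allele and t.gt_alleles() == c.gt_alleles():
                hit = t
                break
        alt = c.alt_alleles[0] if c.alt_alleles else c.ref_allele
        if hit is not None:
            matched_truth.add(id(hit))
            tp += 1
            outcomes.append(Outcome("TP", c.chrom, c.pos, c.ref_allele, alt))
        else:
            fp += 1
            outcomes.append(Outcome("FP", c.chrom, c.pos, c.ref_allele, alt))
    for t in truth_use:
        if id(t) not in matched_truth:
            fn += 1
            alt = t.alt_alleles[0] if t.alt_alleles else t.ref_allele
            outcomes.append(Outcome("FN", t.chrom, t.pos, t.ref_allele, alt))
    return EvalResult(tp, fp, fn), outcomes


def stratified_report(
    calls: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    strata: Dict[str, IntervalSet],
    coverage_bed: Optional[IntervalSet] = None,
    kinds: Sequence[str] = ("SNP", "INDEL"),
) -> pd.DataFrame:
    """One row of metrics per (stratum ∩ coverage, kind)."""
    rows = []
    for name, region in strata.items():
        if region is None:
            raise KeyError(f"unknown stratum {name!r}")
        eff = region.intersect(coverage_bed) if coverage_bed is not None else region
        for kind in kinds:
            res, _ = compare_calls(calls, truth, eff, kind)
            rows.append(
                {
                    "stratum": name,
                    "kind": kind,
                    "tp": res.tp,
                    "fp": res.fp,
                    "fn": res.fn,
                    "precision": res.precision,
                    "recall": res.recall,
                    "f1": res.f1,
                    "fdr": res.fdr,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exon-boundary error profile


def signed_exon_distance(chrom: str, pos: int, exon_set: IntervalSet) -> Optional[int]:
    """Signed distance of ``pos`` to the nearest exon boundary.

    Inside an exon [s, e): min(pos - s, (e-1) - pos) >= 0, so 0 marks a
    terminal exon base. Outside: minus the distance to the nearest exon
    terminal base. Missing (None) when the chromosome has no exons.
    """
    pairs = exon_set.pairs(chrom)
    if not pairs:
        return None
    best: Optional[int] = None
    for s, e in pairs:
        if s <= pos < e:
            return min(pos - s, (e - 1) - pos)
        d = -(s - pos) if pos < s else -(pos - (e - 1))
        if best is None or d > best:  # d is negative; larger = closer
            best = d
    return best


@dataclass
class BoundaryProfile:
    """Mean FN/FP counts per signed exon-boundary distance across samples."""

    distances: List[int]
    fn_mean: List[float]
    fp_mean: List[float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"distance": self.distances, "fn_mean": self.fn_mean,
             "fp_mean": self.fp_mean}
        )


def boundary_profile(
    samples: Sequence[Sequence[Outcome]],
    exon_set: IntervalSet,
    window: Tuple[int, int] = (-50, 50),
) -> BoundaryProfile:
    """Per-distance mean FN and FP counts across per-sample outcome lists."""
    if not samples:
        raise ValueError("need at least one sample")
    lo, hi = window
    dists = list(range(lo, hi + 1))
    fn_tot = Counter()
    fp_tot = Counter()
    for outcomes in samples:
        for o in outcomes:
            d = signed_exon_distance(o.chrom, o.pos, exon_set)
            if d is None or not lo <= d <= hi:
                continue
            if o.outcome == "FN":
                fn_tot[d] += 1
            elif o.outcome == "FP":
                fp_tot[d] += 1
    n = len(samples)
    return BoundaryProfile(
        distances=dists,
        fn_mean=[fn_tot[d] / n for d in dists],
        fp_mean=[fp_tot[d] / n for d in dists],
    )


# ---------------------------------------------------------------------------
# Score thresholding (FDR/TPR)


def threshold_curve(
    calls: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    regions: Optional[IntervalSet] = None,
    score: str = "GQ",
    variant_kind: str = "SNP",
    cap: int = 99,
) -> pd.DataFrame:
    """Recompute TP/FP/FN at every integer score cutoff in [0, cap].

    Returns a frame with columns cutoff, tp, fp, fn, fdr, tpr. FDR is None
    when no calls survive a cutoff.
    """
    if score not in ("GQ", "QUAL"):
        raise ValueError("score must be GQ or QUAL")

    def score_of(rec: VariantRecord) -> float:
        v = rec.gq if score == "GQ" else rec.qual
        return float(v) if v is not None else 0.0

    rows = []
    for t in range(0, cap + 1):
        kept = [c for c in calls if score_of(c) >= t]
        res, _ = compare_calls(kept, truth, regions, variant_kind)
        denom = res.tp + res.fp
        rows.append(
            {
                "cutoff": t,
                "tp": res.tp,
                "fp": res.fp,
                "fn": res.fn,
                "fdr": (res.fp / denom) if denom else None,
                "tpr": res.recall if (res.tp + res.fn) else None,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CutoffResult:
    cutoff: int
    warning: bool  # True when no cutoff reaches the target FDR


def select_cutoff(
    curves: Sequence[pd.DataFrame],
    target_fdr: float = 0.015,
    cap: int = 99,
) -> CutoffResult:
    """Smallest cutoff whose pooled FDR across samples is <= target.

    Pools TP/FP counts over samples at each cutoff. Falls back to the cap
    with a warning flag if the target is never reached.
    """
    if not curves:
        raise ValueError("need at least one threshold curve")
    grid = list(curves[0]["cutoff"])
    for cv in curves[1:]:
        if list(cv["cutoff"]) != grid:
            raise ValueError("threshold curves must share one cutoff grid")
    for t in grid:
        tp = sum(int(cv.loc[cv["cutoff"] == t, "tp"].iloc[0]) for cv in curves)
        fp = sum(int(cv.loc[cv["cutoff"] == t, "fp"].iloc[0]) for cv in curves)
        if tp + fp == 0:
            continue
        if fp / (tp + fp) <= target_fdr:
            return CutoffResult(cutoff=int(t), warning=False)
    return CutoffResult(cutoff=cap, warning=True)
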