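"""Readers and writers for the standard formats the pipeline touches.

Internal convention: 0-based, half-open coordinates everywhere. GTF and VCF
are 1-based on disk; the conversion happens here and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import pysam

from .intervals import GenomicInterval, IntervalSet

log = logging.getLogger(__name__)

_DNA = set("ACGT")


@dataclass
class VariantRecord:
    """A single-sample variant with genotype and per-allele depths.

    ``pos`` is 0-based. ``genotype`` is an unordered pair of allele indices
    (0 = reference) or ``None`` when missing. ``allele_depths`` lists depths
    for the reference allele followed by each alternate allele.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: List[str]
    genotype: Optional[Tuple[int, int]] = None
    qual: Optional[float] = None
    gq: Optional[int] = None
    depth: Optional[int] = None
    allele_depths: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if len(self.ref_allele) < 1:
            raise ValueError("ref_allele must have length >= 1")
        alleles = [self.ref_allele] + list(self.alt_alleles)
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"alleles must be distinct: {alleles}")
        for a in alleles:
            if not a or not set(a) <= _DNA:
                raise ValueError(f"invalid allele {a!r}")
        if self.genotype is not None:
            n = 1 + len(self.alt_alleles)
            if any(i < 0 or i >= n for i in self.genotype):
                raise ValueError(
                    f"genotype indices {self.genotype} out of range for {n} alleles"
                )
            self.genotype = tuple(sorted(self.genotype))  # type: ignore[assignment]

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)

    def gt_alleles(self) -> Optional[Tuple[str, str]]:
        """The genotype as an ordered pair of allele sequences."""
        if self.genotype is None:
            return None
        alleles = [self.ref_allele] + list(self.alt_alleles)
        a, b = (alleles[i] for i in self.genotype)
        return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class EditingSite:
    """A known A-to-I RNA editing position (read out as A>G or T>C).

    On the + strand the genomic reference base is A and edits appear as G;
    on the - strand the genomic base is T and edits appear as C.
    """

    chrom: str
    pos: int
    strand: str
    ref_base: str = "A"
    edited_base: str = "G"

    def __post_init__(self) -> None:
        ok = (self.ref_base, self.edited_base) in {("A", "G"), ("T", "C")}
        if not ok:
            raise ValueError(
                f"not an A-to-I pair: {self.ref_base}>{self.edited_base}"
            )
        if self.strand == "+" and self.ref_base != "A":
            raise ValueError("+ strand editing site must be A>G")
        if self.strand == "-" and self.ref_base != "T":
            raise ValueError("- strand editing site must be T>C")


def is_normalized(ref: str, alt: str) -> bool:
    """True if (ref, alt) is in minimal, left-aligned VCF representation.

    A pair is reducible when both alleles are longer than one base and share
    a trailing base (trimmable suffix) or a leading base beyond the single
    anchor base that indel representation requires.
    """
    if len(ref) > 1 and len(alt) > 1:
        if ref[-1] == alt[-1]:
            return False
        if ref[0] == alt[0]:
            return False
    return True


# ---------------------------------------------------------------------------
# BED


def read_regions(path: str) -> IntervalSet:
    """Read a 3+ column BED file into a merged :class:`IntervalSet`.

    Overlapping and abutting intervals are merged (coverage BEDs are
    run-length encodings). Raises ``ValueError`` naming the offending line
    on malformed input.
    """
    ivs: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {fields[0]}:{start}-{end}"
                )
            ivs.append(GenomicInterval(fields[0], start, end))
    return IntervalSet(ivs)


def write_regions(regions: IntervalSet, path: str) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# GTF

_GTF_FEATURES = ("gene", "transcript", "exon", "CDS")
_GTF_COLUMNS = [
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
]


def read_gene_model(path: str) -> Dict[str, IntervalSet]:
    """Read a GTF and return merged interval sets per feature class.

    Returns a dict with keys ``gene``, ``transcript``, ``exon``, ``CDS``.
    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Rows with other feature types are skipped with a logged count. Which
    positions each stratum contains depends entirely on the annotation
    supplied (e.g. collapsed vs full transcript models).
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_GTF_COLUMNS,
            dtype={"seqname": str, "feature": str, "start": int, "end": int},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_GTF_COLUMNS)
    skipped = int((~df["feature"].isin(_GTF_FEATURES)).sum()) if len(df) else 0
    if skipped:
        log.warning("read_gene_model: skipped %d rows with unknown feature types", skipped)
    out: Dict[str, IntervalSet] = {}
    for feat in _GTF_FEATURES:
        sub = df[df["feature"] == feat] if len(df) else df
        ivs = [
            GenomicInterval(str(r.seqname), int(r.start) - 1, int(r.end),
                            r.strand if r.strand in "+-" else ".")
            for r in sub.itertuples()
        ]
        if feat == "CDS" and not ivs:
            log.warning("read_gene_model: %s contains no CDS rows", path)
        out[feat] = IntervalSet(ivs)
    return out


# ---------------------------------------------------------------------------
# VCF

_VCF_FORMAT_LINES = [
    ('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'),
    ('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (phred)">'),
    ('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'),
    ('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">'),
    ('##FORMAT=<ID=VAF,Number=A,Type=Float,Description="Variant allele fraction">'),
]


def write_vcf(
    records: Sequence[VariantRecord],
    path: str,
    contigs: Dict[str, int],
    sample: str = "SAMPLE",
) -> None:
    """Write single-sample VCF 4.2. ``contigs`` maps name to length.

    Raises ``ValueError`` if a record's contig is absent from ``contigs``.
    VAF is alt depth / total depth, rounded to 3 decimals (display only).
    """
    for rec in records:
        if rec.chrom not in contigs:
            raise ValueError(f"contig {rec.chrom!r} missing from VCF header contigs")
    header = pysam.VariantHeader()
    header.add_line("##source=splicecall")
    for line in _VCF_FORMAT_LINES:
        header.add_line(line)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_sample(sample)
    out = pysam.VariantFile(path, "w", header=header)
    try:
        ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref_allele))
        for rec in ordered:
            v = out.new_record(
                contig=rec.chrom,
                start=rec.pos,
                alleles=tuple([rec.ref_allele] + list(rec.alt_alleles)),
            )
            v.qual = rec.qual
            s = v.samples[sample]
            if rec.genotype is not None:
                s["GT"] = tuple(rec.genotype)
                s.phased = False
            if rec.gq is not None:
                s["GQ"] = int(rec.gq)
            if rec.depth is not None:
                s["DP"] = int(rec.depth)
            if rec.allele_depths is not None:
                s["AD"] = tuple(int(d) for d in rec.allele_depths)
                total = sum(rec.allele_depths)
                if total > 0:
                    s["VAF"] = tuple(
                        round(d / total, 3) for d in rec.allele_depths[1:]
                    )
            out.write(v)
    finally:
        out.close()


def read_vcf(path: str) -> List[VariantRecord]:
    """Read a (single-sample) VCF into :class:`VariantRecord` objects."""
    records: List[VariantRecord] = []
    with pysam.VariantFile(path) as vf:
        sample_names = list(vf.header.samples)
        for v in vf:
            gt = None
            gq = depth = ad = None
            if sample_names:
                s = v.samples[sample_names[0]]
                raw_gt = s.get("GT")
                if raw_gt is not None and None not in raw_gt and len(raw_gt) == 2:
                    gt = tuple(raw_gt)
                gq = s.get("GQ")
                depth = s.get("DP")
                raw_ad = s.get("AD")
                if raw_ad is not None and None not in raw_ad:
                    ad = list(raw_ad)
            records.append(
                VariantRecord(
                    chrom=v.contig,
                    pos=v.start,
                    ref_allele=v.ref,
                    alt_alleles=list(v.alts or ()),
                    genotype=gt,
                    qual=v.qual,
                    gq=int(gq) if gq is not None else None,
                    depth=int(depth) if depth is not None else None,
                    allele_depths=ad,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Editing table (TSV: chrom, pos [1-based], ref, alt, strand[, fraction])


def read_editing_table(path: str) -> List[EditingSite]:
    """Read an A-to-I editing site table.

    Required header columns: chrom, pos (1-based), ref, alt, strand. Rows
    that are not A>G (+ strand) or T>C (- strand) raise a row error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing editing table columns {sorted(missing)}")
    sites: List[EditingSite] = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            sites.append(
                EditingSite(
                    chrom=str(row.chrom),
                    pos=int(row.pos) - 1,
                    strand=str(row.strand),
                    ref_base=str(row.ref).upper(),
                    edited_base=str(row.alt).upper(),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return sites


def write_editing_table(
    sites: Sequence[EditingSite],
    path: str,
    fractions: Optional[Sequence[float]] = None,
) -> None:
    cols = {
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos + 1 for s in sites],
        "ref": [s.ref_base for s in sites],
        "alt": [s.edited_base for s in sites],
        "strand": [s.strand for s in sites],
    }
    if fractions is not None:
        cols["fraction"] = [round(f, 4) for f in fractions]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(path, as_raw=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}
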