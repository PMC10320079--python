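"""Spliced RNA-seq read simulator.

Generates a small diploid genome with multi-exon genes, spikes in truth
SNPs/indels and A-to-I editing sites, and emits coordinate-sorted aligned
reads whose error structure mirrors the things that make RNA-seq variant
calling hard: log-scale per-transcript expression variance, spliced
alignments with N CIGAR gaps, allele-specific expression skew at
heterozygous sites, per-site editing fractions, base-quality-driven
sequencing error and PCR duplicate flags.

Reads are emitted pre-aligned to their generating locus; no aligner is
involved, which isolates caller behaviour from aligner behaviour. All
output is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .formats import (
    EditingSite,
    VariantRecord,
    write_editing_table,
    write_fasta,
    write_regions,
    write_vcf,
)
from .intervals import GenomicInterval, IntervalSet

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# rng stream indices, one per simulation stage (documented seed derivation)
_STAGE_GENOME, _STAGE_TRUTH, _STAGE_READS = 0, 1, 2


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass
class SimConfig:
    """All simulator knobs. Rates are per base pair unless noted."""

    seed: int = 0
    n_genes: int = 50
    n_chroms: int = 4
    exons_per_gene: Tuple[int, int] = (2, 5)
    exon_length: Tuple[int, int] = (80, 220)
    intron_length: Tuple[int, int] = (60, 400)
    snp_rate: float = 0.002
    indel_rate: float = 2e-4
    max_indel_len: int = 6
    editing_site_rate: float = 5e-4
    editing_fraction: Tuple[float, float] = (0.2, 0.9)
    mean_coverage: float = 30.0
    expression_dispersion: float = 0.2
    ase_skew: Tuple[float, float] = (0.3, 0.7)
    read_length: int = 100
    base_error_rate: float = 0.005
    quality_mean: float = 30.0
    quality_sd: float = 5.0
    duplication_rate: float = 0.02
    het_hom_ratio: float = 2.0  # proportion of 0/1 vs 1/1 genotypes

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "editing_site_rate",
                     "base_error_rate", "duplication_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if self.exons_per_gene[0] < 2:
            raise ValueError("exons_per_gene minimum must be >= 2 (multi-exon genes)")
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "editing_fraction", "ase_skew"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"infeasible range for {name}: ({lo}, {hi})")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")
        if self.exon_length[0] < 2 * self.max_indel_len + 10:
            raise ValueError("exon_length minimum too small for max_indel_len")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]          # genomic order, half-open
    cds: List[Tuple[int, int]]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GenomeModel:
    """Reference sequences plus gene structure; the coordinate backbone."""

    sequences: Dict[str, str]
    genes: List[Gene]

    def chrom_lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def exon_set(self) -> IntervalSet:
        return IntervalSet(
            GenomicInterval(g.chrom, s, e) for g in self.genes for s, e in g.exons
        )

    def stratum(self, kind: str) -> IntervalSet:
        """Merged interval set for one of gene/transcript/exon/CDS."""
        if kind in ("gene", "transcript"):
            return IntervalSet(
                GenomicInterval(g.chrom, g.start, g.end) for g in self.genes
            )
        if kind == "exon":
            return self.exon_set()
        if kind == "CDS":
            return IntervalSet(
                GenomicInterval(g.chrom, s, e) for g in self.genes for s, e in g.cds
            )
        raise KeyError(kind)


@dataclass
class TruthSet:
    """Ground-truth variants, editing sites and confident regions."""

    variants: List[VariantRecord]
    editing_sites: List[EditingSite]
    editing_fractions: List[float]
    confident_regions: IntervalSet


# ---------------------------------------------------------------------------
# Genome construction


def make_genome(config: SimConfig) -> GenomeModel:
    """Build a deterministic random genome with multi-exon genes.

    Genes are laid out left to right with random intergenic spacers,
    assigned round-robin to ``n_chroms`` chromosomes. Each gene has one
    transcript; CDS intervals are the exons with UTR trims at both
    transcript ends, so CDS <= exon <= transcript <= gene interval-wise.
    """
    rng = _stage_rng(config.seed, _STAGE_GENOME)
    n_chroms = max(1, min(config.n_chroms, config.n_genes)) if config.n_genes else 1
    chrom_parts: Dict[str, List[str]] = {f"chr{i+1}": [] for i in range(n_chroms)}
    chrom_cursor: Dict[str, int] = {c: 0 for c in chrom_parts}
    genes: List[Gene] = []

    def random_seq(n: int) -> str:
        return "".join(_BASES[rng.integers(0, 4, size=n)])

    for gi in range(config.n_genes):
        chrom = f"chr{(gi % n_chroms) + 1}"
        spacer = int(rng.integers(300, 601))
        chrom_parts[chrom].append(random_seq(spacer))
        chrom_cursor[chrom] += spacer
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons: List[Tuple[int, int]] = []
        pos = chrom_cursor[chrom]
        for ei in range(n_exons):
            if ei > 0:
                ilen = int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
                chrom_parts[chrom].append(random_seq(ilen))
                pos += ilen
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            chrom_parts[chrom].append(random_seq(elen))
            exons.append((pos, pos + elen))
            pos += elen
        chrom_cursor[chrom] = pos
        cds = [list(iv) for iv in exons]
        trim5 = min(30, (exons[0][1] - exons[0][0]) // 3)
        trim3 = min(30, (exons[-1][1] - exons[-1][0]) // 3)
        cds[0][0] += trim5
        cds[-1][1] -= trim3
        genes.append(
            Gene(
                gene_id=f"g{gi+1:04d}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=[(s, e) for s, e in cds if s < e],
            )
        )
    # trailing spacer so reads near the last exon stay inside the contig
    for chrom in chrom_parts:
        chrom_parts[chrom].append(random_seq(300))
    sequences = {c: "".join(parts) for c, parts in sorted(chrom_parts.items())}
    return GenomeModel(sequences=sequences, genes=genes)


def write_gtf(genome: GenomeModel, path: str) -> None:
    """Write the gene models as GTF 2.2 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in genome.genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            rows = [("gene", g.start, g.end), ("transcript", g.start, g.end)]
            rows += [("exon", s, e) for s, e in g.exons]
            rows += [("CDS", s, e) for s, e in g.cds]
            for feat, s, e in rows:
                fh.write(
                    f"{g.chrom}\tsplicecall_sim\t{feat}\t{s+1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Truth variants and editing sites


def spike_truth(genome: GenomeModel, config: SimConfig) -> TruthSet:
    """Place truth SNPs/indels and editing sites in exons.

    Genotypes are drawn 0/1 vs 1/1 at ``het_hom_ratio`` (default 2:1).
    Indels are left-anchored with one reference base and emitted only where
    they are already left-aligned and minimal. Editing sites go only to
    exonic A positions of + strand genes (T for - strand) and never overlap
    a variant.
    """
    rng = _stage_rng(config.seed, _STAGE_TRUTH)
    variants: List[VariantRecord] = []
    editing: List[EditingSite] = []
    fractions: List[float] = []
    occupied: Dict[str, set] = {c: set() for c in genome.sequences}
    p_het = config.het_hom_ratio / (config.het_hom_ratio + 1.0)

    for g in genome.genes:
        seq = genome.sequences[g.chrom]
        for (es, ee) in g.exons:
            pos = es
            while pos < ee:
                u = rng.random()
                if u < config.snp_rate:
                    if any(p in occupied[g.chrom] for p in range(pos - 5, pos + 6)):
                        pos += 1
                        continue
                    ref = seq[pos]
                    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                    gt = (0, 1) if rng.random() < p_het else (1, 1)
                    variants.append(
                        VariantRecord(g.chrom, pos, ref, [alt], genotype=gt)
                    )
                    occupied[g.chrom].update(range(pos - 2, pos + 3))
                elif u < config.snp_rate + config.indel_rate:
                    ilen = int(rng.integers(1, config.max_indel_len + 1))
                    is_ins = rng.random() < 0.5
                    margin = config.max_indel_len + 2
                    if pos < es + margin or pos + ilen + 1 >= ee - margin:
                        pos += 1
                        continue
                    if any(p in occupied[g.chrom]
                           for p in range(pos - 5, pos + ilen + 6)):
                        pos += 1
                        continue
                    anchor = seq[pos]
                    if is_ins:
                        ins = "".join(_BASES[rng.integers(0, 4, size=ilen)])
                        if ins[-1] == anchor:  # would not be left-aligned
                            pos += 1
                            continue
                        ref, alt = anchor, anchor + ins
                        span = 1
                    else:
                        deleted = seq[pos + 1 : pos + 1 + ilen]
                        if deleted[-1] == anchor:
                            pos += 1
                            continue
                        ref, alt = anchor + deleted, anchor
                        span = 1 + ilen
                    gt = (0, 1) if rng.random() < p_het else (1, 1)
                    variants.append(
                        VariantRecord(g.chrom, pos, ref, [alt], genotype=gt)
                    )
                    occupied[g.chrom].update(range(pos - 2, pos + span + 2))
                pos += 1
        # editing sites in a second pass so they never collide with variants
        target = "A" if g.strand == "+" else "T"
        edited = "G" if g.strand == "+" else "C"
        for (es, ee) in g.exons:
            for pos in range(es, ee):
                if seq[pos] != target or pos in occupied[g.chrom]:
                    continue
                if rng.random() < config.editing_site_rate:
                    editing.append(
                        EditingSite(g.chrom, pos, g.strand, target, edited)
                    )
                    fractions.append(
                        float(rng.uniform(*config.editing_fraction))
                    )
                    occupied[g.chrom].add(pos)

    confident = genome.exon_set().pad(10, genome.chrom_lengths())
    return TruthSet(
        variants=variants,
        editing_sites=editing,
        editing_fractions=fractions,
        confident_regions=confident,
    )


# ---------------------------------------------------------------------------
# Read simulation

# a haplotype transcript is a list of alignment ops against the reference:
#   ("M", ref_start, ref_len, query_seq)   ref_len == len(query_seq)
#   ("I", anchor_ref_pos, 0, inserted_seq)
#   ("D", ref_start, del_len, "")
#   ("N", ref_start, intron_len, "")
_Op = Tuple[str, int, int, str]


def _haplotype_ops(gene: Gene, seq: str,
                   variants: Sequence[VariantRecord], hap: int) -> List[_Op]:
    """Alignment ops of one haplotype's spliced transcript vs the reference.

    Haplotype 1 carries the alternate allele at heterozygous sites; both
    haplotypes carry it at homozygous-alt sites.
    """
    by_pos = {v.pos: v for v in variants}
    ops: List[_Op] = []
    prev_exon_end: Optional[int] = None
    for (es, ee) in gene.exons:
        if prev_exon_end is not None and es > prev_exon_end:
            ops.append(("N", prev_exon_end, es - prev_exon_end, ""))
        prev_exon_end = ee
        pos = es
        buf: List[str] = []
        buf_start = pos
        while pos < ee:
            v = by_pos.get(pos)
            applies = v is not None and (
                v.genotype == (1, 1) or (v.genotype == (0, 1) and hap == 1)
            )
            if not applies:
                buf.append(seq[pos])
                pos += 1
                continue
            ref, alt = v.ref_allele, v.alt_alleles[0]
            if len(ref) == 1 and len(alt) == 1:        # SNP
                buf.append(alt)
                pos += 1
            elif len(alt) > len(ref):                  # insertion
                buf.append(seq[pos])
                if buf:
                    ops.append(("M", buf_start, len(buf), "".join(buf)))
                ops.append(("I", pos, 0, alt[1:]))
                buf, buf_start = [], pos + 1
                pos += 1
            else:                                      # deletion
                buf.append(seq[pos])
                ops.append(("M", buf_start, len(buf), "".join(buf)))
                dlen = len(ref) - 1
                ops.append(("D", pos + 1, dlen, ""))
                buf, buf_start = [], pos + 1 + dlen
                pos += 1 + dlen
        if buf:
            ops.append(("M", buf_start, len(buf), "".join(buf)))
    return ops


@dataclass
class SimRead:
    """One simulated aligned read (reference-forward orientation)."""

    name: str
    chrom: str
    pos: int
    cigar: List[Tuple[str, int]]
    seq: str
    quals: np.ndarray
    is_reverse: bool
    is_duplicate: bool = False


def _slice_read(ops: Sequence[_Op], t0: int, length: int):
    """Cut a read of ``length`` query bases starting at transcript offset t0.

    Returns (ref_start, cigar, seq_parts, mblocks) where mblocks are
    (ref_pos, read_offset, run_len) for aligned-match runs; or None if the
    slice yields no aligned bases. Leading/trailing insertions are trimmed
    (a real alignment cannot start or end with I), which may shorten the
    read.
    """
    t1 = t0 + length
    qpos = 0
    cigar: List[Tuple[str, int]] = []
    seq_parts: List[str] = []
    mblocks: List[Tuple[int, int, int]] = []
    read_len = 0
    ref_start = None
    for op, rstart, rlen, q in ops:
        if op in ("M", "I"):
            q_end = qpos + len(q)
            a, b = max(t0, qpos), min(t1, q_end)
            if a < b:
                sub = q[a - qpos : b - qpos]
                if op == "M":
                    rp = rstart + (a - qpos)
                    if ref_start is None:
                        ref_start = rp
                    cigar.append(("M", b - a))
                    mblocks.append((rp, read_len, b - a))
                else:
                    cigar.append(("I", b - a))
                seq_parts.append(sub)
                read_len += b - a
            qpos = q_end
            if qpos >= t1:
                break
        else:  # D or N: sits between query coords; include only mid-read
            if t0 < qpos < t1:
                cigar.append((op, rlen))
    while cigar and cigar[0][0] in ("I", "D", "N"):
        op, ln = cigar.pop(0)
        if op == "I":
            first = seq_parts.pop(0)
            assert len(first) == ln
            read_len -= ln
            mblocks = [(rp, off - ln, n) for rp, off, n in mblocks]
    while cigar and cigar[-1][0] in ("I", "D", "N"):
        op, ln = cigar.pop(-1)
        if op == "I":
            last = seq_parts.pop(-1)
            assert len(last) == ln
            read_len -= ln
    if not cigar or ref_start is None:
        return None
    ref_start = mblocks[0][0]
    return ref_start, cigar, "".join(seq_parts), mblocks


def simulate_reads(
    genome: GenomeModel, truth: TruthSet, config: SimConfig
) -> List[SimRead]:
    """Simulate aligned spliced reads for every gene.

    Per transcript: depth multiplier ~ LogNormal(0, dispersion); an ASE
    skew drawn uniformly from the configured range gives the per-read
    probability of sampling haplotype 1 (the alt-bearing haplotype at het
    sites). Editing sites flip their base per read at the site's editing
    fraction; sequencing errors are i.i.d. per base. Reads are returned
    sorted by (chrom, pos, name).
    """
    rng = _stage_rng(config.seed, _STAGE_READS)
    var_by_gene: Dict[str, List[VariantRecord]] = {g.gene_id: [] for g in genome.genes}
    gene_index: List[Tuple[str, int, int, Gene]] = [
        (g.chrom, g.start, g.end, g) for g in genome.genes
    ]
    for v in truth.variants:
        for chrom, s, e, g in gene_index:
            if chrom == v.chrom and s <= v.pos < e:
                var_by_gene[g.gene_id].append(v)
                break
    edits_by_gene: Dict[str, List[Tuple[int, str, float]]] = {
        g.gene_id: [] for g in genome.genes
    }
    for site, frac in zip(truth.editing_sites, truth.editing_fractions):
        for chrom, s, e, g in gene_index:
            if chrom == site.chrom and s <= site.pos < e:
                edits_by_gene[g.gene_id].append((site.pos, site.edited_base, frac))
                break

    reads: List[SimRead] = []
    for g in genome.genes:
        seq = genome.sequences[g.chrom]
        gvars = sorted(var_by_gene[g.gene_id], key=lambda v: v.pos)
        gedits = edits_by_gene[g.gene_id]
        ops_by_hap = [
            _haplotype_ops(g, seq, gvars, hap) for hap in (0, 1)
        ]
        qlens = [
            sum(len(q) for op, _, _, q in ops if op in ("M", "I"))
            for ops in ops_by_hap
        ]
        skew = float(rng.uniform(*config.ase_skew))
        mult = (
            float(rng.lognormal(0.0, config.expression_dispersion))
            if config.expression_dispersion > 0
            else 1.0
        )
        mean_qlen = (qlens[0] + qlens[1]) / 2.0
        n_reads = int(round(config.mean_coverage * mult * mean_qlen / config.read_length))
        serial = 0
        gene_reads: List[SimRead] = []
        for _ in range(n_reads):
            hap = 1 if rng.random() < skew else 0
            qlen = qlens[hap]
            if qlen < config.read_length:
                continue
            t0 = int(rng.integers(0, qlen - config.read_length + 1))
            sliced = _slice_read(ops_by_hap[hap], t0, config.read_length)
            if sliced is None:
                continue
            ref_start, cigar, rseq, mblocks = sliced
            if len(rseq) < 20:
                continue
            bases = np.frombuffer(rseq.encode(), dtype=np.uint8).copy()
            # RNA editing: per-read flip at each covered editing site
            for epos, ebase, frac in gedits:
                for rp, off, n in mblocks:
                    if rp <= epos < rp + n:
                        if rng.random() < frac:
                            bases[off + (epos - rp)] = ord(ebase)
                        break
            # sequencing errors
            if config.base_error_rate > 0:
                errs = np.nonzero(rng.random(len(bases)) < config.base_error_rate)[0]
                for i in errs:
                    cur = chr(bases[i])
                    bases[i] = ord(str(rng.choice([b for b in "ACGT" if b != cur])))
            quals = np.clip(
                np.rint(rng.normal(config.quality_mean, config.quality_sd, len(bases))),
                2, 40,
            ).astype(np.int32)
            serial += 1
            gene_reads.append(
                SimRead(
                    name=f"{g.gene_id}_r{serial:05d}",
                    chrom=g.chrom,
                    pos=ref_start,
                    cigar=cigar,
                    seq=bases.tobytes().decode(),
                    quals=quals,
                    is_reverse=bool(rng.random() < 0.5),
                )
            )
        # PCR duplicates: flagged copies of existing reads
        if config.duplication_rate > 0:
            for r in list(gene_reads):
                if rng.random() < config.duplication_rate:
                    gene_reads.append(
                        SimRead(
                            name=r.name + "_dup",
                            chrom=r.chrom,
                            pos=r.pos,
                            cigar=list(r.cigar),
                            seq=r.seq,
                            quals=r.quals.copy(),
                            is_reverse=r.is_reverse,
                            is_duplicate=True,
                        )
                    )
        reads.extend(gene_reads)
    reads.sort(key=lambda r: (r.chrom, r.pos, r.name))
    return reads


_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "=": 7, "X": 8}


def write_bam(reads: Sequence[SimRead], genome: GenomeModel, path: str) -> None:
    """Write coordinate-sorted BAM plus .bai index."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in sorted(genome.chrom_lengths().items())
        ],
    }
    tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r.name
            a.reference_id = tid[r.chrom]
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigartuples = [(_CIGAR_CODE[op], ln) for op, ln in r.cigar]
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            a.flag = (0x10 if r.is_reverse else 0) | (0x400 if r.is_duplicate else 0)
            bam.write(a)
    pysam.index(path)


def simulate_dataset(config: SimConfig, out_dir: str) -> Dict[str, str]:
    """Run the full simulation and write every artifact to ``out_dir``.

    Writes reference FASTA, GTF, coordinate-sorted BAM (+index), truth VCF,
    editing-site TSV and confident-regions BED. Returns the path map.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    genome = make_genome(config)
    truth = spike_truth(genome, config)
    reads = simulate_reads(genome, truth, config)
    paths = {
        "fasta": os.path.join(out_dir, "reference.fa"),
        "gtf": os.path.join(out_dir, "genes.gtf"),
        "bam": os.path.join(out_dir, "reads.bam"),
        "truth_vcf": os.path.join(out_dir, "truth.vcf"),
        "editing_tsv": os.path.join(out_dir, "editing_sites.tsv"),
        "confident_bed": os.path.join(out_dir, "confident_regions.bed"),
        "config_json": os.path.join(out_dir, "sim_config.json"),
    }
    write_fasta(genome.sequences, paths["fasta"])
    write_gtf(genome, paths["gtf"])
    write_bam(reads, genome, paths["bam"])
    write_vcf(truth.variants, paths["truth_vcf"], genome.chrom_lengths())
    write_editing_table(truth.editing_sites, paths["editing_tsv"],
                        truth.editing_fractions)
    write_regions(truth.confident_regions, paths["confident_bed"])
    config.to_json(paths["config_json"])
    return paths
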