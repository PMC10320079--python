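"""Benchmark harness: run the pipeline on the fixed scenarios and measure.

Everything here recomputes its numbers from scratch by simulating data,
training, calling and evaluating; tests and the reproduction script share
these entry points so they always measure the same conditions.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .candidates import CandidateSite, scan_region
from .encode import EncoderConfig, PileupExample, make_labeled_examples
from .evaluate import compare_calls, coverage_regions
from .formats import read_fasta, read_regions, read_vcf
from .genotyper import ClassifierModel, GenotypeCall, call_pipeline, train
from .intervals import IntervalSet
from .read_prep import ReadSegment, load_segments
from .scenarios import (
    HELDOUT_CHROMS,
    TRAIN_CHROMS,
    TUNE_CHROMS,
    clean_germline_config,
    editing_rich_config,
    noiseless_config,
)
from .sim import SimConfig, simulate_dataset


@dataclass
class Dataset:
    """Paths plus loaded reference/truth for one simulated dataset."""

    paths: Dict[str, str]
    reference: Dict[str, str]

    @classmethod
    def simulate(cls, config: SimConfig, out_dir: str) -> "Dataset":
        paths = simulate_dataset(config, out_dir)
        return cls(paths=paths, reference=read_fasta(paths["fasta"]))

    def truth_variants(self):
        return read_vcf(self.paths["truth_vcf"])

    def confident_regions(self) -> IntervalSet:
        return read_regions(self.paths["confident_bed"])


def dataset_segments(ds: Dataset, chroms: Sequence[str]) -> Dict[str, List[ReadSegment]]:
    return {c: load_segments(ds.paths["bam"], chrom=c) for c in chroms}


def labeled_examples_for(
    ds: Dataset,
    chroms: Sequence[str],
    encoder: Optional[EncoderConfig] = None,
) -> List[PileupExample]:
    """Candidates -> labelled pileup examples for the given chromosomes."""
    cfg = encoder or EncoderConfig()
    truth = ds.truth_variants()
    confident = ds.confident_regions()
    out: List[PileupExample] = []
    for chrom, segments in dataset_segments(ds, chroms).items():
        if not segments:
            continue
        ref = ds.reference[chrom]
        cands = scan_region(segments, chrom, 0, len(ref), ref)
        out.extend(
            make_labeled_examples(cands, truth, segments, ds.reference, cfg, confident)
        )
    return out


def eval_regions(ds: Dataset, min_depth: int = 3,
                 chroms: Optional[Sequence[str]] = None) -> IntervalSet:
    """Confident regions intersected with the min-depth coverage BED."""
    cov = coverage_regions(ds.paths["bam"], min_depth=min_depth, chroms=chroms)
    return ds.confident_regions().intersect(cov)


# ---------------------------------------------------------------------------
# Scenario runs


def run_noiseless(seed: int, n_genes: int = 30, out_dir: Optional[str] = None):
    """Noiseless-limit run: candidate completeness and Bayes GT accuracy.

    Returns a dict with ``candidate_completeness`` (fraction of exonic
    truth SNPs with >= 2 alt-supporting reads that are proposed as
    candidates) and ``bayes_gt_accuracy`` (fraction of truth SNPs with
    >= 3 covering and >= 2 alt-supporting reads whose end-to-end call has
    the correct genotype).
    """
    with tempfile.TemporaryDirectory() as tmp:
        ds = Dataset.simulate(noiseless_config(seed=seed, n_genes=n_genes),
                              out_dir or os.path.join(tmp, "noiseless"))
        chroms = sorted(ds.reference)
        segs = dataset_segments(ds, chroms)
        truth = [t for t in ds.truth_variants() if t.is_snp]

        def alt_support(t) -> Tuple[int, int]:
            from .candidates import build_pileup

            cols = build_pileup(segs[t.chrom], t.chrom, t.pos, t.pos + 1,
                                ds.reference[t.chrom])
            if not cols:
                return 0, 0
            obs = cols[0].obs(("SNP", t.alt_alleles[0]))
            return cols[0].depth, obs.count if obs else 0

        cands: Dict[Tuple[str, int], CandidateSite] = {}
        for chrom in chroms:
            ref = ds.reference[chrom]
            for c in scan_region(segs[chrom], chrom, 0, len(ref), ref):
                if c.kind == "SNP":
                    cands[(c.chrom, c.pos)] = c

        eligible = []
        for t in truth:
            depth, alt_n = alt_support(t)
            if alt_n >= 2:
                eligible.append((t, depth, alt_n))
        n_proposed = sum(
            1 for t, _, _ in eligible
            if (t.chrom, t.pos) in cands
            and t.alt_alleles[0] in cands[(t.chrom, t.pos)].alt_alleles
        )
        completeness = n_proposed / len(eligible) if eligible else None

        model = ClassifierModel(backend="bayes-baseline",
                                params={"mean_base_error": 0.001})
        calls = call_pipeline(ds.paths["bam"], ds.reference, model)
        call_by_site = {(c.chrom, c.pos): c for c in calls}
        scored = [
            (t, call_by_site.get((t.chrom, t.pos)))
            for t, depth, alt_n in eligible
            if depth >= 3
        ]
        correct = sum(
            1 for t, c in scored
            if c is not None
            and c.alt_alleles[0] == t.alt_alleles[0]
            and c.genotype == t.genotype
        )
        gt_accuracy = correct / len(scored) if scored else None
        return {
            "candidate_completeness": completeness,
            "bayes_gt_accuracy": gt_accuracy,
            "n_truth_snps": len(truth),
            "n_eligible": len(eligible),
        }


def train_on_dataset(ds: Dataset, seed: int,
                     backend: str = "logistic") -> ClassifierModel:
    examples = labeled_examples_for(ds, list(TRAIN_CHROMS) + list(TUNE_CHROMS))
    return train(examples, backend=backend,
                 split=(TRAIN_CHROMS, TUNE_CHROMS), seed=seed)


def heldout_calls(ds: Dataset, model: ClassifierModel) -> List[GenotypeCall]:
    return call_pipeline(ds.paths["bam"], ds.reference, model,
                         chroms=list(HELDOUT_CHROMS))


def run_clean_germline(seed: int, n_genes: int = 200,
                       out_dir: Optional[str] = None) -> Dict:
    """Train logistic on chr1-2 (tune chr3), call held-out chr4, report SNP
    F1 inside CDS regions with >= 3x coverage."""
    from .formats import read_gene_model

    with tempfile.TemporaryDirectory() as tmp:
        ds = Dataset.simulate(clean_germline_config(seed=seed, n_genes=n_genes),
                              out_dir or os.path.join(tmp, "clean"))
        model = train_on_dataset(ds, seed=seed)
        calls = heldout_calls(ds, model)
        truth = ds.truth_variants()
        cds = read_gene_model(ds.paths["gtf"])["CDS"]
        regions = eval_regions(ds, min_depth=3, chroms=list(HELDOUT_CHROMS)).intersect(cds)
        res, outcomes = compare_calls(
            [c.to_variant_record() for c in calls], truth, regions, "SNP"
        )
        return {
            "snp_f1": res.f1,
            "snp_precision": res.precision,
            "snp_recall": res.recall,
            "tp": res.tp, "fp": res.fp, "fn": res.fn,
            "outcomes": outcomes,
            "model": model,
        }


def run_editing_comparison(seed: int, n_genes: int = 200,
                           out_dir: Optional[str] = None) -> Dict:
    """Editing-rich scenario: FP calls at editing sites, trained vs Bayes.

    Editing sites carry no DNA variant, so any variant call at one is a
    false positive. Training data label them hom-ref (they are absent from
    the truth VCF), which is the mechanism by which the learned backend
    can suppress them; the Bayes baseline sees only allele counts and
    cannot.
    """
    from .formats import read_editing_table

    with tempfile.TemporaryDirectory() as tmp:
        ds = Dataset.simulate(editing_rich_config(seed=seed, n_genes=n_genes),
                              out_dir or os.path.join(tmp, "editing"))
        trained = train_on_dataset(ds, seed=seed)
        bayes = ClassifierModel(backend="bayes-baseline",
                                params={"mean_base_error": 0.005})
        sites = {
            (s.chrom, s.pos)
            for s in read_editing_table(ds.paths["editing_tsv"])
            if s.chrom in HELDOUT_CHROMS
        }
        regions = eval_regions(ds, min_depth=3, chroms=list(HELDOUT_CHROMS))

        def editing_fp(model: ClassifierModel) -> int:
            calls = heldout_calls(ds, model)
            return sum(
                1 for c in calls
                if (c.chrom, c.pos) in sites
                and regions.contains(c.chrom, c.pos)
            )

        fp_trained = editing_fp(trained)
        fp_bayes = editing_fp(bayes)
        return {
            "editing_fp_trained": fp_trained,
            "editing_fp_bayes": fp_bayes,
            "n_heldout_editing_sites": len(sites),
        }
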