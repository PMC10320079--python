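import numpy as np
import pandas as pd
import pytest

from splicecall.evaluate import (
    EvalResult,
    Outcome,
    boundary_profile,
    compare_calls,
    coverage_regions,
    precision_recall_f1,
    select_cutoff,
    signed_exon_distance,
    stratified_report,
    threshold_curve,
)
from splicecall.formats import VariantRecord
from splicecall.intervals import GenomicInterval, IntervalSet


def V(pos, ref="A", alt="G", gt=(0, 1), chrom="chr1", gq=None, qual=None):
    return VariantRecord(chrom, pos, ref, [alt], genotype=gt, gq=gq, qual=qual)


ALL = IntervalSet([GenomicInterval("chr1", 0, 10_000)])


# ---------------------------------------------------------------------------
# Metrics


def test_metric_formulas_and_missing():
    p, r, f1 = precision_recall_f1(2, 1, 1)
    assert (p, r) == (2 / 3, 2 / 3)
    assert f1 == pytest.approx(2 / 3)
    assert precision_recall_f1(0, 0, 5) == (None, 0.0, None)
    assert precision_recall_f1(0, 0, 0) == (None, None, None)
    with pytest.raises(ValueError):
        EvalResult(-1, 0, 0)


def test_published_precision_values():
    """Precision at the strict GQ cutoff reproduces the reported values."""
    p_snp, _, _ = precision_recall_f1(9077, 18, 0)
    assert round(p_snp, 3) == 0.998
    p_indel, _, _ = precision_recall_f1(86, 1, 0)
    assert round(p_indel, 3) == 0.989


def test_fdr_is_one_minus_precision():
    r = EvalResult(8, 2, 5)
    assert r.fdr == pytest.approx(1 - r.precision)


# ---------------------------------------------------------------------------
# compare_calls


def test_basic_concordance():
    truth = [V(10), V(20), V(30)]
    calls = [V(10), V(20), V(50)]
    res, outcomes = compare_calls(calls, truth, ALL, "SNP")
    assert (res.tp, res.fp, res.fn) == (2, 1, 1)
    assert res.precision == res.recall == pytest.approx(2 / 3)
    kinds = {(o.outcome, o.pos) for o in outcomes}
    assert ("FP", 50) in kinds and ("FN", 30) in kinds


def test_genotype_mismatch_counts_both_ways():
    truth = [V(10, gt=(0, 1))]
    calls = [V(10, gt=(1, 1))]
    res, _ = compare_calls(calls, truth, ALL, "SNP")
    assert (res.tp, res.fp, res.fn) == (0, 1, 1)


def test_empty_calls_all_fn():
    truth = [V(10), V(20)]
    res, _ = compare_calls([], truth, ALL, "SNP")
    assert (res.tp, res.fp, res.fn) == (0, 0, 2)


def test_hom_ref_and_out_of_region_ignored():
    truth = [V(10)]
    calls = [V(10), V(20, gt=(0, 0)), V(9000, chrom="chr2")]
    region = IntervalSet([GenomicInterval("chr1", 0, 100)])
    res, _ = compare_calls(calls, truth, region, "SNP")
    assert (res.tp, res.fp, res.fn) == (1, 0, 0)


def test_kind_filter_separates_snp_indel():
    truth = [V(10), V(20, ref="AT", alt="A")]
    calls = [V(10), V(20, ref="AT", alt="A")]
    snp, _ = compare_calls(calls, truth, ALL, "SNP")
    indel, _ = compare_calls(calls, truth, ALL, "INDEL")
    assert (snp.tp, indel.tp) == (1, 1)
    assert snp.tp + snp.fn == 1


def test_unnormalized_record_rejected():
    truth = [V(10)]
    calls = [V(10, ref="ATT", alt="AT")]
    with pytest.raises(ValueError, match="normaliz"):
        compare_calls(calls, truth, ALL, "INDEL")


def test_symmetry_swapping_calls_and_truth():
    truth = [V(10), V(20), V(30, gt=(1, 1))]
    calls = [V(10), V(30, gt=(0, 1)), V(50)]
    a, _ = compare_calls(calls, truth, ALL, "SNP")
    b, _ = compare_calls(truth, calls, ALL, "SNP")
    assert (a.tp, a.fp, a.fn) == (b.tp, b.fn, b.fp)


def test_conservation_tp_plus_fn_is_truth_count():
    truth = [V(p) for p in (10, 20, 30, 40)]
    calls = [V(10), V(25), V(30, gt=(1, 1))]
    res, _ = compare_calls(calls, truth, ALL, "SNP")
    assert res.tp + res.fn == 4


# ---------------------------------------------------------------------------
# Coverage


def test_coverage_regions_threshold_runs(tmp_path, toy_genome):
    from splicecall.sim import SimRead, write_bam

    # depths: pos 0 has 2 reads, pos 1-2 have 3, pos 3 has 2
    reads = [
        SimRead("a", "chr1", 0, [("M", 3)], "ACG", np.array([30] * 3), False),
        SimRead("b", "chr1", 0, [("M", 4)], "ACGT", np.array([30] * 4), False),
        SimRead("c", "chr1", 1, [("M", 3)], "CGT", np.array([30] * 3), False),
    ]
    path = str(tmp_path / "cov.bam")
    write_bam(reads, toy_genome, path)
    cov = coverage_regions(path, min_depth=3)
    assert cov.pairs("chr1") == [(1, 3)]
    assert len(coverage_regions(path, min_depth=5)) == 0
    whole = coverage_regions(path, min_depth=0)
    assert whole.pairs("chr1") == [(0, len(toy_genome.sequences["chr1"]))]


def test_coverage_excludes_duplicates(tmp_path, toy_genome):
    from splicecall.sim import SimRead, write_bam

    reads = [
        SimRead("a", "chr1", 0, [("M", 3)], "ACG", np.array([30] * 3), False),
        SimRead("a_dup", "chr1", 0, [("M", 3)], "ACG", np.array([30] * 3),
                False, is_duplicate=True),
    ]
    path = str(tmp_path / "dup.bam")
    write_bam(reads, toy_genome, path)
    assert len(coverage_regions(path, min_depth=2)) == 0


# ---------------------------------------------------------------------------
# Stratified report


def test_stratified_report_consistency():
    truth = [V(10), V(120)]
    calls = [V(10), V(120), V(130)]
    strata = {
        "all": ALL,
        "left": IntervalSet([GenomicInterval("chr1", 0, 100)]),
    }
    df = stratified_report(calls, truth, strata, kinds=["SNP"])
    whole = df[df.stratum == "all"].iloc[0]
    direct, _ = compare_calls(calls, truth, ALL, "SNP")
    assert (whole.tp, whole.fp, whole.fn) == (direct.tp, direct.fp, direct.fn)
    left = df[df.stratum == "left"].iloc[0]
    assert (left.tp, left.fp, left.fn) == (1, 0, 0)


def test_strata_containment(noiseless_ds):
    """CDS truth count <= exon truth count (CDS is inside exons)."""
    from splicecall.formats import read_gene_model

    strata = read_gene_model(noiseless_ds.paths["gtf"])
    truth = noiseless_ds.truth_variants()
    df = stratified_report(truth, truth, {"CDS": strata["CDS"],
                                          "exon": strata["exon"]},
                           kinds=["SNP"])
    cds = df[df.stratum == "CDS"].iloc[0]
    exon = df[df.stratum == "exon"].iloc[0]
    assert cds.tp <= exon.tp
    assert cds.tp + cds.fn <= exon.tp + exon.fn


def test_unknown_stratum_errors():
    with pytest.raises(KeyError):
        stratified_report([], [], {"mystery": None})


# ---------------------------------------------------------------------------
# Exon distance / boundary profile


def test_signed_exon_distance_convention():
    exons = IntervalSet([GenomicInterval("chr1", 100, 200)])
    assert signed_exon_distance("chr1", 100, exons) == 0
    assert signed_exon_distance("chr1", 199, exons) == 0
    assert signed_exon_distance("chr1", 97, exons) == -3
    assert signed_exon_distance("chr1", 120, exons) == 20
    assert signed_exon_distance("chr1", 202, exons) == -3
    assert signed_exon_distance("chr2", 120, exons) is None


def test_signed_exon_distance_nearest_of_two():
    exons = IntervalSet([GenomicInterval("chr1", 0, 10),
                         GenomicInterval("chr1", 100, 110)])
    assert signed_exon_distance("chr1", 12, exons) == -3
    assert signed_exon_distance("chr1", 97, exons) == -3


def test_boundary_profile_means():
    exons = IntervalSet([GenomicInterval("chr1", 100, 200)])
    # two samples with 2 and 0 FPs at distance 5 -> mean 1.0
    s1 = [Outcome("FP", "chr1", 105, "A", "G"),
          Outcome("FP", "chr1", 105, "A", "G")]
    s2 = []
    prof = boundary_profile([s1, s2], exons, window=(-10, 10))
    df = prof.as_frame().set_index("distance")
    assert df.loc[5, "fp_mean"] == 1.0
    assert df.loc[0, "fn_mean"] == 0.0
    prof1 = boundary_profile([[Outcome("FP", "chr1", 100, "A", "G")]], exons)
    assert prof1.as_frame().set_index("distance").loc[0, "fp_mean"] == 1.0


def test_boundary_profile_needs_samples():
    with pytest.raises(ValueError):
        boundary_profile([], IntervalSet([]))


# ---------------------------------------------------------------------------
# Threshold curve and cutoff selection


def test_threshold_curve_by_definition():
    truth = [V(10)]
    calls = [V(10, gq=30), V(50, gq=5)]
    curve = threshold_curve(calls, truth, ALL, score="GQ", variant_kind="SNP")
    row18 = curve[curve.cutoff == 18].iloc[0]
    assert (row18.tp, row18.fp, row18.fdr, row18.tpr) == (1, 0, 0.0, 1.0)
    row0 = curve[curve.cutoff == 0].iloc[0]
    direct, _ = compare_calls(calls, truth, ALL, "SNP")
    assert (row0.tp, row0.fp, row0.fn) == (direct.tp, direct.fp, direct.fn)
    beyond = curve[curve.cutoff == 99].iloc[0]
    assert beyond.fdr is None or np.isnan(beyond.fdr)
    assert beyond.tpr == 0.0


def test_threshold_monotonicity_full_grid(noiseless_ds):
    """FP(t) and TP(t) never increase as the cutoff rises."""
    from splicecall.genotyper import ClassifierModel, call_pipeline

    model = ClassifierModel(backend="bayes-baseline",
                            params={"mean_base_error": 0.001})
    calls = [c.to_variant_record()
             for c in call_pipeline(noiseless_ds.paths["bam"],
                                    noiseless_ds.reference, model)]
    truth = noiseless_ds.truth_variants()
    curve = threshold_curve(calls, truth, None, score="GQ", variant_kind="SNP")
    assert (curve.tp.diff().dropna() <= 0).all()
    assert (curve.fp.diff().dropna() <= 0).all()


def _curve_with_first_pass_at_18():
    """100 TPs at GQ 50 plus 2 FPs at GQ 17: FDR 0.0196 below 18, 0 at 18."""
    truth = [V(i * 10) for i in range(1, 101)]
    calls = [V(i * 10, gq=50) for i in range(1, 101)]
    calls += [V(5000 + i, gq=17) for i in range(2)]
    return threshold_curve(calls, truth, ALL, score="GQ", variant_kind="SNP")


def test_select_cutoff_at_18():
    curve = _curve_with_first_pass_at_18()
    res = select_cutoff([curve], target_fdr=0.015)
    assert res.cutoff == 18 and not res.warning


def test_select_cutoff_all_tp_is_zero():
    truth = [V(10)]
    calls = [V(10, gq=40)]
    curve = threshold_curve(calls, truth, ALL)
    res = select_cutoff([curve], target_fdr=0.015)
    assert res.cutoff == 0 and not res.warning


def test_select_cutoff_never_reached_warns():
    truth = []
    calls = [V(10, gq=40)]  # always a pure FP
    curve = threshold_curve(calls, truth, ALL)
    res = select_cutoff([curve], target_fdr=0.015)
    assert res.cutoff == 99 and res.warning


def test_select_cutoff_pools_across_samples():
    c1 = _curve_with_first_pass_at_18()
    res = select_cutoff([c1, c1], target_fdr=0.015)
    assert res.cutoff == 18
    with pytest.raises(ValueError):
        select_cutoff([], target_fdr=0.015)
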