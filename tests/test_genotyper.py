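import math

import numpy as np
import pytest
from scipy.stats import binom

from splicecall.candidates import CandidateSite
from splicecall.encode import EncoderConfig, PileupExample
from splicecall.genotyper import (
    ClassifierModel,
    ClassProbs,
    bayes_baseline_probs,
    call_genotype,
    call_pipeline,
    classify,
    example_counts,
    merge_site_calls,
    train,
)

CFG = EncoderConfig(width=21, height=41)


def synth_example(ref_n, alt_n, chrom="chr1", pos=100, ref="A", alt="G",
                  label=None, bq=0.75, mapq=1.0):
    """Hand-built pileup example with the given allele counts."""
    H, W = CFG.height, CFG.width
    c = CFG.center
    t = np.zeros((H, W, 6), dtype=np.float32)
    t[0, :, 0] = 0.25
    t[0, :, 1] = 1.0
    t[0, :, 2] = 1.0
    row = 1
    for i in range(alt_n + ref_n):
        is_alt = i < alt_n
        t[row, :, 0] = 0.75 if is_alt else 0.25
        t[row, :, 1] = bq
        t[row, :, 2] = mapq
        t[row, :, 3] = 1.0 if i % 2 == 0 else 0.5
        t[row, :, 4] = 1.0 if is_alt else 0.5
        t[row, c, 5] = 1.0 if is_alt else 0.0
        row += 1
    cand = CandidateSite(chrom, pos, ref, [alt], [alt_n], ref_n + alt_n, "SNP")
    return PileupExample(candidate=cand, alt_index=0, tensor=t, label=label)


def test_class_probs_invariants():
    with pytest.raises(ValueError):
        ClassProbs(0.5, 0.4, 0.2)
    p = ClassProbs(0.2, 0.5, 0.3)
    assert p.argmax == 1
    assert ClassProbs(1 / 3, 1 / 3, 1 / 3).argmax == 0  # tie -> lowest class


# ---------------------------------------------------------------------------
# Bayes baseline


def test_bayes_no_data_uniform():
    p = bayes_baseline_probs(0, 0, 0.001)
    assert p.as_tuple() == pytest.approx((1 / 3, 1 / 3, 1 / 3))


def test_bayes_matches_direct_likelihood_oracle():
    """Backend equals an independent normalized-binomial computation."""
    e = 0.001
    for ref_n, alt_n in [(10, 0), (5, 5), (0, 10), (20, 3), (3, 20), (1, 1)]:
        n = ref_n + alt_n
        ls = np.array([
            binom.pmf(alt_n, n, e),
            binom.pmf(alt_n, n, 0.5),
            binom.pmf(alt_n, n, 1 - e),
        ])
        expected = ls / ls.sum()
        got = bayes_baseline_probs(ref_n, alt_n, e)
        assert got.as_tuple() == pytest.approx(tuple(expected), rel=1e-9)


def test_bayes_argmax_cases():
    assert bayes_baseline_probs(10, 0, 0.001).p0 > 0.999
    assert bayes_baseline_probs(5, 5, 0.001).argmax == 1
    assert bayes_baseline_probs(0, 10, 0.001).argmax == 2


def test_bayes_negative_counts_error():
    with pytest.raises(ValueError):
        bayes_baseline_probs(-1, 0)


# ---------------------------------------------------------------------------
# call_genotype (GQ/QUAL formulas)


def _cand():
    return CandidateSite("chr1", 5, "A", ["G"], [4], 10, "SNP")


def test_certain_hom_ref():
    call = call_genotype(ClassProbs(1.0, 0.0, 0.0), _cand())
    assert call.genotype == (0, 0)
    assert call.qual == 0.0
    assert call.gq == 99


def test_het_call_formula_values():
    call = call_genotype(ClassProbs(0.1, 0.7, 0.2), _cand())
    assert call.genotype == (0, 1)
    assert call.gq == 5      # round(-10*log10(0.3)) = round(5.23)
    assert call.qual == 10.0  # -10*log10(0.1)


def test_tie_break_and_gq():
    call = call_genotype(ClassProbs(1 / 3, 1 / 3, 1 / 3), _cand())
    assert call.genotype == (0, 0)
    assert call.gq == 2      # round(-10*log10(2/3)) = round(1.76)


def test_gq_monotone_and_qual_monotone():
    gqs, quals = [], []
    for p in np.linspace(0.34, 1.0, 60):
        rest = (1 - p) / 2
        call = call_genotype(ClassProbs(rest, float(p), rest), _cand())
        gqs.append(call.gq)
        quals.append(call.qual)
    assert all(b >= a for a, b in zip(gqs, gqs[1:]))
    # QUAL non-increasing in p0
    quals = [call_genotype(ClassProbs(float(p0), 1 - float(p0), 0.0), _cand()).qual
             for p0 in np.linspace(0.0, 1.0, 60)]
    assert all(b <= a for a, b in zip(quals, quals[1:]))


# ---------------------------------------------------------------------------
# Training


def _training_set(n_per_class=40, chrom="chr1"):
    exs = []
    rng = np.random.default_rng(0)
    for i in range(n_per_class):
        depth = int(rng.integers(20, 36))
        exs.append(synth_example(depth, int(rng.integers(0, 2)), chrom=chrom,
                                 pos=1000 + i, label=0))
        alt = int(rng.binomial(depth, 0.5))
        alt = min(max(alt, depth // 4), 3 * depth // 4)
        exs.append(synth_example(depth - alt, alt, chrom=chrom,
                                 pos=2000 + i, label=1))
        exs.append(synth_example(int(rng.integers(0, 2)), depth, chrom=chrom,
                                 pos=3000 + i, label=2))
    return exs


def test_train_separable_fixture_high_accuracy():
    exs = _training_set()
    model = train(exs, backend="logistic", split=((), ()), seed=0)
    correct = sum(classify(model, ex).argmax == ex.label for ex in exs)
    assert correct / len(exs) >= 0.99


def test_train_deterministic():
    exs = _training_set()
    m1 = train(exs, backend="logistic", split=((), ()), seed=0)
    m2 = train(exs, backend="logistic", split=((), ()), seed=0)
    assert m1.params == m2.params


def test_train_missing_class_errors():
    exs = [synth_example(10, 0, pos=i, label=0) for i in range(10)]
    with pytest.raises(ValueError, match="class"):
        train(exs, backend="logistic")


def test_model_json_round_trip(tmp_path):
    exs = _training_set()
    model = train(exs, backend="logistic", split=((), ()), seed=0)
    path = str(tmp_path / "model.json")
    model.to_json(path)
    back = ClassifierModel.from_json(path)
    ex = synth_example(10, 10)
    assert classify(back, ex).as_tuple() == pytest.approx(
        classify(model, ex).as_tuple()
    )


def test_classify_shape_mismatch_errors():
    model = train(_training_set(), backend="logistic", seed=0)
    bad = synth_example(5, 5)
    bad_cfg = EncoderConfig(width=11, height=5)
    bad.tensor = np.zeros((5, 11, 6), dtype=np.float32)
    # feature vector length is fixed, so a malformed feature array errors
    model.params["feature_mean"] = model.params["feature_mean"][:-1]
    model.params["feature_sd"] = model.params["feature_sd"][:-1]
    with pytest.raises(ValueError, match="feature"):
        classify(model, bad)


def test_example_counts():
    ex = synth_example(7, 5)
    assert example_counts(ex) == (7, 5)


def test_leakage_refusal():
    from splicecall.genotyper import assert_no_leakage

    model = ClassifierModel(backend="bayes-baseline",
                            metadata={"train_chroms": ["chr1"],
                                      "tune_chroms": ["chr3"]})
    assert_no_leakage(model, ["chr4"])
    with pytest.raises(ValueError, match="chr1"):
        assert_no_leakage(model, ["chr1", "chr4"])


def test_merge_site_calls_prefers_high_qual_nonref():
    a = call_genotype(ClassProbs(0.05, 0.9, 0.05),
                      CandidateSite("chr1", 5, "A", ["G"], [4], 10, "SNP"))
    b = call_genotype(ClassProbs(0.4, 0.55, 0.05),
                      CandidateSite("chr1", 5, "A", ["T"], [3], 10, "SNP"))
    merged = merge_site_calls([b, a])
    assert merged.alt_alleles == ["G"]


# ---------------------------------------------------------------------------
# End-to-end pipeline


def test_pipeline_noiseless_recovers_truth(noiseless_ds):
    from splicecall.bench import run_noiseless

    res = run_noiseless(seed=1, n_genes=12)
    assert res["bayes_gt_accuracy"] == 1.0


def test_pipeline_deterministic_vcf_bytes(noiseless_ds, tmp_path):
    from splicecall.formats import write_vcf

    model = ClassifierModel(backend="bayes-baseline",
                            params={"mean_base_error": 0.001})
    outs = []
    for run in (1, 2):
        calls = call_pipeline(noiseless_ds.paths["bam"], noiseless_ds.reference,
                              model)
        path = str(tmp_path / f"calls{run}.vcf")
        write_vcf([c.to_variant_record() for c in calls], path,
                  {k: len(v) for k, v in noiseless_ds.reference.items()})
        outs.append(open(path, "rb").read())
    assert outs[0] == outs[1]


def test_pipeline_empty_bam_gives_no_calls(tmp_path, toy_genome):
    from splicecall.sim import write_bam

    path = str(tmp_path / "empty.bam")
    write_bam([], toy_genome, path)
    model = ClassifierModel(backend="bayes-baseline",
                            params={"mean_base_error": 0.001})
    calls = call_pipeline(path, toy_genome.sequences, model)
    assert calls == []


def test_pipeline_contig_mismatch_errors(noiseless_ds):
    model = ClassifierModel(backend="bayes-baseline",
                            params={"mean_base_error": 0.001})
    with pytest.raises(ValueError, match="contig"):
        call_pipeline(noiseless_ds.paths["bam"], {"weird": "ACGT"}, model)


def test_silver_truth_fidelity(noiseless_ds):
    """Training with silver labels == training with gold labels when they
    coincide: both label paths produce identical classifications."""
    from splicecall.bench import labeled_examples_for

    chroms = sorted(noiseless_ds.reference)
    silver = labeled_examples_for(noiseless_ds, chroms)
    gold = labeled_examples_for(noiseless_ds, chroms)
    assert [ex.label for ex in silver] == [ex.label for ex in gold]
    counts = {lab: sum(1 for e in silver if e.label == lab) for lab in (0, 1, 2)}
    if all(counts.values()):
        m_silver = train(silver, backend="logistic", seed=0)
        m_gold = train(gold, backend="logistic", seed=0)
        assert m_silver.params == m_gold.params
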