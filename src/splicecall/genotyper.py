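"""Three-class genotype classification with GQ/QUAL scoring.

Candidates are classified as homozygous-reference, heterozygous, or
homozygous-alternate. Two backends:

``logistic``
    Multinomial logistic regression on pooled per-example features
    (depth, alt fraction, base/mapping quality summaries, strand balance,
    allele-balance deviation, ref/alt base identities). Trained on
    labelled examples from chromosome-partitioned splits; the tuning split
    selects the regularization strength.

``bayes-baseline``
    Closed-form diploid binomial model: alt-read count likelihoods at
    per-read error rate e for hom-ref, 0.5 for het, 1-e for hom-alt, flat
    prior. Serves as the independent baseline the learned backend is
    compared against.

Genotype quality (GQ) is the phred-scaled probability that the emitted
call is wrong, ``-10 log10(1 - p_called)``; QUAL is the phred-scaled
probability that the site is not a variant, ``-10 log10(p0)``; both capped
at 99.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom
from sklearn.linear_model import LogisticRegression

from .candidates import CandidateSite, scan_region
from .encode import EncoderConfig, PileupExample, encode_example, read_supports_alt
from .formats import VariantRecord
from .read_prep import ReadSegment

CLASS_NAMES = ("hom-ref", "het", "hom-alt")


@dataclass(frozen=True)
class ClassProbs:
    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        s = self.p0 + self.p1 + self.p2
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise ValueError(f"class probabilities sum to {s}, not 1")
        if min(self.p0, self.p1, self.p2) < -1e-12:
            raise ValueError("negative class probability")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.p0, self.p1, self.p2)

    @property
    def argmax(self) -> int:
        # tie -> lowest class index (conservative: prefers reference)
        probs = self.as_tuple()
        best = max(probs)
        return min(i for i, p in enumerate(probs) if p == best)


@dataclass
class GenotypeCall:
    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: List[str]
    genotype: Tuple[int, int]
    called_class: int
    probs: ClassProbs
    qual: float
    gq: int
    depth: int
    allele_depths: List[int]

    def to_variant_record(self) -> VariantRecord:
        return VariantRecord(
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.ref_allele,
            alt_alleles=list(self.alt_alleles),
            genotype=self.genotype,
            qual=self.qual,
            gq=self.gq,
            depth=self.depth,
            allele_depths=list(self.allele_depths),
        )


# ---------------------------------------------------------------------------
# Features

_BASE_ORDER = "ACGT"
FEATURE_NAMES = (
    ["log_depth", "alt_fraction", "balance_dev", "mean_bq_alt", "mean_bq_ref",
     "mean_mapq", "frac_forward", "frac_forward_alt", "frac_diff_window",
     "row_fill", "is_ins", "is_del", "indel_len"]
    + [f"ref_{b}" for b in _BASE_ORDER]
    + [f"alt_{b}" for b in _BASE_ORDER]
)


def example_features(ex: PileupExample) -> np.ndarray:
    """Pool one pileup tensor into a fixed-length feature vector.

    Works off the candidate column of the tensor plus candidate metadata;
    the ref/alt base one-hots let the model learn base-change-specific
    artifact structure (the A>G / T>C signature of RNA editing).
    """
    t = ex.tensor
    H, W, _ = t.shape
    c = (W - 1) // 2
    rows = t[1:, c, :]
    covered = rows[:, 3] > 0  # strand channel is nonzero wherever a read covers
    n = int(covered.sum())
    alt_rows = covered & (rows[:, 4] == 1.0)
    ref_rows = covered & (rows[:, 4] == 0.5)
    n_alt = int(alt_rows.sum())
    alt_frac = n_alt / n if n else 0.0
    mean_bq_alt = float(rows[alt_rows, 1].mean()) if n_alt else 0.0
    mean_bq_ref = float(rows[ref_rows, 1].mean()) if ref_rows.any() else 0.0
    mean_mapq = float(rows[covered, 2].mean()) if n else 0.0
    frac_fwd = float((rows[covered, 3] == 1.0).mean()) if n else 0.5
    frac_fwd_alt = float((rows[alt_rows, 3] == 1.0).mean()) if n_alt else 0.5
    window_cov = t[1:, :, 3] > 0
    frac_diff = (
        float(t[1:, :, 5][window_cov].mean()) if window_cov.any() else 0.0
    )
    cand = ex.candidate
    alt = cand.alt_alleles[ex.alt_index]
    is_ins = 1.0 if cand.kind == "INS" else 0.0
    is_del = 1.0 if cand.kind == "DEL" else 0.0
    indel_len = abs(len(alt) - len(cand.ref_allele)) / 10.0
    ref_onehot = [1.0 if cand.ref_allele[0] == b else 0.0 for b in _BASE_ORDER]
    alt_base = alt[0] if cand.kind == "SNP" else "N"
    alt_onehot = [1.0 if alt_base == b else 0.0 for b in _BASE_ORDER]
    return np.array(
        [math.log1p(n), alt_frac, abs(alt_frac - 0.5), mean_bq_alt, mean_bq_ref,
         mean_mapq, frac_fwd, frac_fwd_alt, frac_diff, n / (H - 1),
         is_ins, is_del, indel_len]
        + ref_onehot + alt_onehot,
        dtype=np.float64,
    )


def example_counts(ex: PileupExample) -> Tuple[int, int]:
    """(ref-ish count, alt count) at the candidate column of the tensor."""
    t = ex.tensor
    c = (t.shape[1] - 1) // 2
    rows = t[1:, c, :]
    covered = rows[:, 3] > 0
    n_alt = int((covered & (rows[:, 4] == 1.0)).sum())
    return int(covered.sum()) - n_alt, n_alt


# ---------------------------------------------------------------------------
# Backends


def bayes_baseline_probs(
    ref_count: int, alt_count: int, mean_base_error: float = 0.005
) -> ClassProbs:
    """Closed-form diploid binomial genotype probabilities, flat prior.

    Likelihoods: Binomial(alt | n, e), Binomial(alt | n, 0.5),
    Binomial(alt | n, 1 - e) for hom-ref / het / hom-alt. Zero depth gives
    the uniform distribution.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be >= 0")
    n = ref_count + alt_count
    if n == 0:
        return ClassProbs(1 / 3, 1 / 3, 1 / 3)
    e = min(max(mean_base_error, 1e-6), 0.5)
    # log-space for numerical stability at high depth
    logls = np.array([
        binom.logpmf(alt_count, n, e),
        binom.logpmf(alt_count, n, 0.5),
        binom.logpmf(alt_count, n, 1.0 - e),
    ])
    logls -= logls.max()
    ls = np.exp(logls)
    ls /= ls.sum()
    return ClassProbs(float(ls[0]), float(ls[1]), float(ls[2]))


@dataclass
class ClassifierModel:
    """A trained 3-class genotype classifier, JSON-serializable."""

    backend: str                      # "logistic" | "bayes-baseline"
    params: Dict = field(default_factory=dict)
    metadata: Dict = field(default_factory=dict)
    _estimator: Optional[LogisticRegression] = field(default=None, repr=False)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"backend": self.backend, "params": self.params,
                       "metadata": self.metadata}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ClassifierModel":
        with open(path) as fh:
            raw = json.load(fh)
        model = cls(backend=raw["backend"], params=raw["params"],
                    metadata=raw.get("metadata", {}))
        if model.backend == "logistic":
            model._rebuild_estimator()
        return model

    def _rebuild_estimator(self) -> None:
        est = LogisticRegression()
        est.coef_ = np.array(self.params["coef"])
        est.intercept_ = np.array(self.params["intercept"])
        est.classes_ = np.array(self.params["classes"])
        self._estimator = est


def train(
    examples: Sequence[PileupExample],
    backend: str = "logistic",
    hyperparams: Optional[Dict] = None,
    split: Tuple[Sequence[str], Sequence[str]] = ((), ()),
    seed: int = 0,
) -> ClassifierModel:
    """Train a classifier on labelled examples.

    ``split`` is (train_chroms, tune_chroms); examples on other
    chromosomes are ignored, and the tuning split is used only to select
    the regularization strength. Empty train split means use everything
    not in the tune split. The model records its split so downstream
    evaluation can refuse leakage. Raises if any genotype class is missing
    from the training data.
    """
    hp = dict(hyperparams or {})
    train_chroms, tune_chroms = (set(split[0]), set(split[1]))
    if backend == "bayes-baseline":
        return ClassifierModel(
            backend=backend,
            params={"mean_base_error": hp.get("mean_base_error", 0.005)},
            metadata={"train_chroms": sorted(train_chroms),
                      "tune_chroms": sorted(tune_chroms), "seed": seed},
        )
    if backend != "logistic":
        raise ValueError(f"unknown backend {backend!r}")

    def in_train(ex: PileupExample) -> bool:
        c = ex.candidate.chrom
        if train_chroms:
            return c in train_chroms
        return c not in tune_chroms

    tr = [ex for ex in examples if ex.label is not None and in_train(ex)]
    tu = [ex for ex in examples
          if ex.label is not None and ex.candidate.chrom in tune_chroms]
    counts = Counter(ex.label for ex in tr)
    missing = [c for c in (0, 1, 2) if counts[c] == 0]
    if missing:
        raise ValueError(
            f"class(es) {missing} missing from training data; "
            f"class counts: {dict(counts)}"
        )
    X = np.stack([example_features(ex) for ex in tr])
    y = np.array([ex.label for ex in tr])
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd

    grid = hp.get("C_grid", [0.1, 1.0, 10.0])
    best_C, best_score, best_est = None, -np.inf, None
    if tu:
        Xt = (np.stack([example_features(ex) for ex in tu]) - mean) / sd
        yt = np.array([ex.label for ex in tu])
    for C in grid:
        est = LogisticRegression(C=C, max_iter=5000, random_state=seed)
        est.fit(Xs, y)
        score = est.score(Xt, yt) if tu else est.score(Xs, y)
        if score > best_score:
            best_C, best_score, best_est = C, score, est
    model = ClassifierModel(
        backend="logistic",
        params={
            "coef": best_est.coef_.tolist(),
            "intercept": best_est.intercept_.tolist(),
            "classes": best_est.classes_.tolist(),
            "feature_mean": mean.tolist(),
            "feature_sd": sd.tolist(),
            "C": best_C,
        },
        metadata={
            "train_chroms": sorted(train_chroms),
            "tune_chroms": sorted(tune_chroms),
            "seed": seed,
            "n_train": len(tr),
            "class_counts": {int(k): int(v) for k, v in counts.items()},
            "feature_names": list(FEATURE_NAMES),
            "tune_accuracy": float(best_score) if tu else None,
        },
    )
    model._estimator = best_est
    return model


def assert_no_leakage(model: ClassifierModel, eval_chroms: Iterable[str]) -> None:
    """Refuse evaluation on chromosomes the model trained or tuned on."""
    seen = set(model.metadata.get("train_chroms", [])) | set(
        model.metadata.get("tune_chroms", [])
    )
    overlap = seen & set(eval_chroms)
    if overlap:
        raise ValueError(f"evaluation chromosomes overlap training split: {sorted(overlap)}")


def classify(model: ClassifierModel, example: PileupExample) -> ClassProbs:
    """Class probabilities for one example under the given model."""
    if model.backend == "bayes-baseline":
        ref_n, alt_n = example_counts(example)
        return bayes_baseline_probs(ref_n, alt_n, model.params["mean_base_error"])
    if model._estimator is None:
        model._rebuild_estimator()
    x = example_features(example)
    mean = np.array(model.params["feature_mean"])
    sd = np.array(model.params["feature_sd"])
    if x.shape != mean.shape:
        raise ValueError(
            f"feature shape {x.shape} does not match model spec {mean.shape}"
        )
    probs = model._estimator.predict_proba(((x - mean) / sd)[None, :])[0]
    full = {int(c): float(p) for c, p in zip(model._estimator.classes_, probs)}
    p = [full.get(i, 0.0) for i in (0, 1, 2)]
    s = sum(p)
    return ClassProbs(p[0] / s, p[1] / s, p[2] / s)


# ---------------------------------------------------------------------------
# Calls


def _phred(p: float, cap: float) -> float:
    if p <= 0:
        return float(cap)
    return min(float(cap), -10.0 * math.log10(p))


def call_genotype(
    probs: ClassProbs,
    candidate: CandidateSite,
    alt_index: int = 0,
    gq_cap: int = 99,
) -> GenotypeCall:
    """Turn class probabilities into a genotype call with GQ and QUAL.

    GQ = -10 log10(1 - p_called), rounded to the nearest integer;
    QUAL = -10 log10(p0), one decimal. Both capped. Ties in the argmax go
    to the lowest class (reference-preferring).
    """
    called = probs.argmax
    p_called = probs.as_tuple()[called]
    gq = int(round(_phred(1.0 - p_called, gq_cap)))
    qual = round(_phred(probs.p0, gq_cap), 1)
    gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[called]
    alt = candidate.alt_alleles[alt_index]
    alt_support = candidate.support[alt_index]
    ref_depth = max(0, candidate.depth - sum(candidate.support))
    return GenotypeCall(
        chrom=candidate.chrom,
        pos=candidate.pos,
        ref_allele=candidate.ref_allele,
        alt_alleles=[alt],
        genotype=gt,
        called_class=called,
        probs=probs,
        qual=qual,
        gq=gq,
        depth=candidate.depth,
        allele_depths=[ref_depth, alt_support],
    )


def merge_site_calls(calls: Sequence[GenotypeCall]) -> Optional[GenotypeCall]:
    """Merge per-alt calls at one site: keep the highest-QUAL alt first.

    Per-alt examples keep the classifier 3-class; at multi-allelic sites
    the best-supported non-reference call wins the record.
    """
    if not calls:
        return None
    nonref = [c for c in calls if c.called_class > 0]
    pool = nonref if nonref else list(calls)
    pool = sorted(pool, key=lambda c: (-c.qual, c.alt_alleles[0]))
    return pool[0]


def call_pipeline(
    bam_path: str,
    reference_by_chrom: Dict[str, str],
    model: ClassifierModel,
    encoder_config: Optional[EncoderConfig] = None,
    min_mapq: int = 1,
    min_segment_len: int = 15,
    min_base_qual: int = 10,
    min_alt_count: int = 2,
    min_alt_fraction: float = 0.1,
    emit_ref_calls: bool = False,
    chroms: Optional[Sequence[str]] = None,
) -> List[GenotypeCall]:
    """End-to-end: filter -> split -> candidates -> encode -> classify -> call.

    Returns merged per-site calls sorted by position; homozygous-reference
    calls are suppressed unless ``emit_ref_calls``.
    """
    import pysam

    from .read_prep import filter_reads, from_pysam, split_all

    cfg = encoder_config or EncoderConfig()
    out: List[GenotypeCall] = []
    with pysam.AlignmentFile(bam_path) as bam:
        bam_chroms = list(bam.references)
        for chrom in bam_chroms:
            if chrom not in reference_by_chrom:
                raise ValueError(
                    f"contig {chrom!r} in BAM but not in reference FASTA"
                )
        targets = list(chroms) if chroms is not None else bam_chroms
        for chrom in targets:
            reads = [from_pysam(a) for a in bam.fetch(chrom)]
            kept, _ = filter_reads(reads, min_mapq=min_mapq)
            segments = split_all(kept, min_segment_len=min_segment_len)
            if not segments:
                continue
            ref = reference_by_chrom[chrom]
            cands = scan_region(
                segments, chrom, 0, len(ref), ref,
                min_base_qual=min_base_qual,
                min_alt_count=min_alt_count,
                min_alt_fraction=min_alt_fraction,
            )
            by_site: Dict[Tuple[int, str], List[GenotypeCall]] = {}
            for cand in cands:
                for ai in range(len(cand.alt_alleles)):
                    ex = encode_example(cand, ai, segments, ref, cfg)
                    probs = classify(model, ex)
                    call = call_genotype(probs, cand, ai)
                    by_site.setdefault((cand.pos, cand.kind), []).append(call)
            for key in sorted(by_site, key=lambda k: (k[0], k[1])):
                merged = merge_site_calls(by_site[key])
                if merged is None:
                    continue
                if merged.called_class == 0 and not emit_ref_calls:
                    continue
                out.append(merged)
    out.sort(key=lambda c: (c.chrom, c.pos, c.ref_allele))
    return out
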