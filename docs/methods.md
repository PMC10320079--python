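# Methods

## Problem and scope

`splicecall` calls diploid germline genotypes (hom-ref / het / hom-alt)
at candidate SNP and small-indel sites from spliced short-read RNA-seq
alignments, and quantifies the behaviour of such a caller under the error
sources specific to RNA: expression-driven coverage variation,
allele-specific expression (ASE), splice-interrupted read context, PCR
duplication and A-to-I RNA editing. Everything runs at desk scale on
simulated data; no external datasets, aligners or GPU training are
involved.

## Read preparation

Spliced aligners encode introns as SKIP (`N`) CIGAR operations. All
downstream stages work on intron-free segments, so each read is split
into one segment per maximal `N`-free CIGAR run. The partition is exact:
concatenating segment bases/qualities reproduces the parent, and the
per-base reference→base map of the segments equals the parent's (both are
property-tested). Choices the format leaves open:

* segments with fewer than `min_segment_len` aligned bases (default 15)
  are dropped — a 3-base exon overhang carries no usable variant context;
* a deletion adjacent to an `N` stays inside its segment; an insertion at
  a segment boundary attaches to the left segment;
* default read filter: unmapped/secondary/supplementary/duplicate flags
  and MAPQ < 1 (excludes multimappers).

A CIGAR beginning or ending with `N` is treated as malformed.

## Candidate discovery

Per-column pileup over split segments. Bases under `min_base_qual`
(default 10) count toward depth but not allele support. Insertions and
deletions are tallied at their left anchor base (VCF convention,
left-aligned). An alternate allele becomes a candidate iff

* count ≥ `min_alt_count` (default 2), and
* count / depth ≥ `min_alt_fraction` (default 0.10).

The count rule alone is meaningless at RNA coverage extremes (2 reads out
of 10 000 are noise), hence the fraction gate; both are configurable. At
most two alternates are kept per site and kind (by count, then
lexicographic); deletion sites keep one alternate because deletions of
different lengths need different REF alleles. No local haplotype
realignment is performed; indel support is read directly from segment
CIGARs. This is a deliberate simplification — on simulated reads emitted
pre-aligned it is lossless, on real aligner output it would miss indels
the aligner represented inconsistently.

## Example encoding

Each (candidate, alt) pair becomes a H×W×6 tensor, H = 101 rows (row 0 is
the reference track), W = 221 columns centred on the candidate, values in
[0, 1]:

| channel | content | values |
|---|---|---|
| 0 | base identity | A 0.25, C 0.50, G 0.75, T 1.00, gap/pad 0 |
| 1 | base quality | min(q, 40)/40 |
| 2 | mapping quality | min(mapq, 60)/60 |
| 3 | strand | forward 1.0, reverse 0.5, pad 0 |
| 4 | supports scored alt | yes 1.0, no 0.5, pad 0 |
| 5 | differs from reference | 1.0 / 0 |

Rows are sorted by (start, name); overflow beyond H−1 reads is
downsampled uniformly with a fixed seed, so encoding is deterministic.
The channel set and value conventions are this package's own; the
defaults keep memory trivial and are configurable.

Labels for training come from a genotyped truth VCF ("silver truth" when
that VCF was itself produced by a trusted caller on matched DNA):
candidates matching a truth variant take the truth genotype with respect
to the scored alt; candidates inside the confident regions with no truth
match are labelled hom-ref; candidates outside the confident regions are
excluded. In simulation the truth VCF is exact, so silver and gold labels
coincide; the test suite wires both label paths and checks they agree —
passing this says the plumbing is consistent, not that noisy silver
labels are harmless.

## Genotype classification

Backends share one interface (example → simplex over 3 classes):

* **bayes-baseline** (closed form): with n = ref+alt reads at the
  candidate column and per-read error e, class likelihoods are
  Binom(alt | n, e), Binom(alt | n, ½), Binom(alt | n, 1−e) with a flat
  prior, computed in log space. n = 0 returns the uniform distribution.
  This is the right model when reads are independent and error is the
  only confounder — exactly what ASE, editing and duplication break, which
  is why it is the comparison baseline.
* **logistic** (default trained backend): multinomial logistic regression
  (scikit-learn, lbfgs) on pooled per-example features: log depth, alt
  fraction, |alt fraction − ½|, mean alt/ref base quality, mean MAPQ,
  strand fractions, window mismatch fraction, row fill, indel kind and
  length, and one-hot ref/alt base identities. The base one-hots are what
  allow the model to learn base-change-specific artifact structure (the
  A>G / T>C editing signature); the pooled-feature design trades the full
  tensor's spatial context for desk-scale training. Features are
  z-scored; the regularization strength C is selected from {0.1, 1, 10}
  on the tuning split. Training records its chromosome split and
  `assert_no_leakage` refuses evaluation on those chromosomes.

A convolutional backend over the full tensor is a natural extension; it
is out of scope here because the pooled features already expose the
signals the desk-scale benchmarks exercise and no deep-learning framework
is among the dependencies.

Training/tuning/evaluation are partitioned by chromosome (defaults:
train chr1–2, tune chr3, hold out chr4) so no locus contributes to both
fitting and measurement.

**Scores.** Called class = argmax (ties → lowest class, i.e. prefer
reference). GQ = min(99, round(−10·log₁₀(1 − p_called))) — the phred
probability the call is wrong; QUAL = min(99, −10·log₁₀(p₀)), one
decimal — the phred probability the site is not a variant. Multi-allelic
sites are scored one alt at a time and merged, highest-QUAL alt first.

## Evaluation

Matching is **normalized genotype concordance**: same chromosome and
position, identical alleles after left-aligned minimal representation,
identical unordered genotype. A genotype mismatch at matching alleles
counts one FP *and* one FN. Haplotype-resolved matching (vcfeval-style)
is deliberately out of scope; concordance is exact on simulator output
because the simulator emits normalized truth, but it will undercount
matches on call sets with complex representation differences
(MNP decomposition, unnormalized indels — the latter raise an error).

Coverage stratification computes the ≥ `min_depth` (default 3×) BED from
the query BAM *after* the caller's read filters, so "callable" means what
the caller could actually see; the same region set filters calls and
truth uniformly. The exon-boundary profile uses a signed distance: inside
an exon [s, e), d = min(pos−s, (e−1)−pos) ≥ 0 with 0 at terminal bases;
outside, d = −(bases to the nearest terminal base); ties across exons
take the smaller |d|. Any fixed anchoring convention yields the same
profile shape.

Threshold curves recompute TP/FP/FN at every integer cutoff of GQ or
QUAL in [0, 99]; the selected cutoff is the smallest whose FDR pooled
over samples (summed TP/FP) meets the target, default 1.5% — favouring
precision over sensitivity, as production pipelines usually do. If the
target is never met the cap is returned with a warning flag rather than
silently passing everything.

## Editing annotation and isoforms

The cross-tab counts SNP evaluation outcomes (TP/FP/FN) by the 12
ordered base changes and by exact-position membership in an editing-site
table; membership is position-only so allele-aware and position-only
views are both recoverable from the output. Codon isoform enumeration
treats unphased genotypes as free combinations and editing as optional
per molecule (edited and unedited bases both possible), takes the
Cartesian product over the three positions, reverse-complements
minus-strand contexts, transcribes and translates with the standard
genetic code (stops reported as `*`).

## Simulator

What it emulates, per transcript: depth multiplier ~ LogNormal(0, σ)
(σ = `expression_dispersion`, default 0.2); ASE skew drawn uniformly from
`ase_skew` (default U[0.3, 0.7]) giving the per-read probability of the
alt-bearing haplotype; per-site editing fractions ~ U[0.2, 0.9]; i.i.d.
base errors at `base_error_rate` with qualities ~ N(30, 5²) clipped to
[2, 40]; PCR duplicates as flagged copies at `duplication_rate`. Genes
have 2–5 exons of 80–220 bp with 60–400 bp introns; truth variants are
exonic, het:hom 2:1, indels ≤ 6 bp emitted only where already
left-aligned and minimal; editing sites sit at exonic A (+ strand) / T
(− strand) positions disjoint from variants. The ASE and editing-fraction
distributions are conventions, not measurements — tune them per question.
Confident regions default to exons padded by 10 bp.

Reads are emitted **pre-aligned to their generating locus** with exact
junction CIGARs; there is no aligner, no soft-clipping, no mismapping, no
strand-specific library structure, no fragment-length model, no 3′
degradation. Consequently, passing benchmarks here shows the caller's
logic is correct under the modelled noise; it says nothing about
robustness to alignment artifacts, reference bias or library chemistry,
which dominate error on real data. All outputs are byte-deterministic
given the config seed; stage randomness derives from one seed via
`numpy.random.SeedSequence(seed, spawn_key=(stage,))`.

## Benchmark scenarios and problem sizes

Fixed in `splicecall.scenarios` and shared by the tests and
`scripts/acceptance.py`:

* **noiseless** (30 genes, error 0, dispersion 0, ASE 0.5, no editing):
  candidate discovery must propose every truth SNP with ≥ 2 supporting
  reads, and the Bayes baseline must genotype correctly every truth SNP
  with ≥ 3 covering and ≥ 2 alt reads. Below that support, a het site
  whose few reads are all-alt is mathematically indistinguishable from
  hom-alt — no caller can resolve it, so the accuracy gate conditions on
  identifiable sites.
* **clean_germline** (200 genes over 4 chromosomes, 30×, error 0.005,
  dispersion 0.2, ASE U[0.3, 0.7], no editing): logistic backend trained
  on chr1–2 (tune chr3) is measured on held-out chr4, SNP F1 in
  CDS ∩ ≥3× regions. Editing is excluded here on purpose so this scenario
  isolates germline genotyping accuracy from artifact suppression.
* **editing_rich** (as above plus editing sites at 10⁻³ per exonic A/T):
  editing sites are absent from the truth VCF, so training labels them
  hom-ref; the measurement is the number of FP calls at held-out editing
  sites for the trained backend versus the Bayes baseline. The trained
  model suppresses a fraction of them (via the base-change and
  allele-balance features) at some cost in A>G/T>C het recall — the same
  precision-for-recall trade a context-aware caller makes.

These sizes keep any single benchmark under ~15 s on one CPU while
leaving enough truth sites (≈50 SNPs and ≈10 editing sites on the
held-out chromosome) for the comparisons to be meaningful; they are
scaled-down study conditions, not tuned quantities.

## Numerical and degenerate-input choices

Binomial likelihoods in log space (stable at high depth); error rate
clamped to [10⁻⁶, 0.5]; GQ/QUAL capped at 99 with p = 0 mapping to the
cap; empty pileups are valid all-pad examples, not errors; zero-depth
columns produce no candidates; metrics with zero denominators are
reported as missing (None), never as 0; undefined FDR rows are skipped in
cutoff pooling. Interval sets merge abutting intervals (coverage BEDs are
run-length encodings) and all internal coordinates are 0-based half-open,
converted only at GTF/VCF boundaries.

## Known limitations

* No haplotype-resolved truth matching; representation-sensitive on real
  call sets.
* No local realignment; indel handling trusts the input CIGARs.
* Pooled-feature classifier cannot use spatial context beyond the
  candidate column summaries (e.g. homopolymer runs, junction proximity).
* The simulator's independence assumptions (i.i.d. errors, per-read
  editing, flag-only duplicates) understate correlated error on real
  instruments.
* Single-sample VCF semantics only; no phasing, MNVs or structural
  variants.
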