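"""Fixed simulation scenarios used by the benchmark suite.

Three study conditions, fixed up front so tests and the reproduction
script exercise identical data:

* ``noiseless``    — error-free, undispersed, unskewed reads; the limit in
  which candidate discovery must be complete and the Bayes baseline must
  genotype perfectly.
* ``clean_germline`` — a 200-gene genome at 30x with 0.5% base error and
  realistic expression dispersion/ASE, no editing; measures germline
  genotyping accuracy on a held-out chromosome.
* ``editing_rich`` — the same error structure plus abundant A-to-I editing
  sites; measures whether a trained classifier learns to suppress editing
  artifacts that the Bayes baseline calls as variants.
"""

from __future__ import annotations

from .sim import SimConfig

# chromosome-partitioned split for training/tuning/held-out evaluation
TRAIN_CHROMS = ("chr1", "chr2")
TUNE_CHROMS = ("chr3",)
HELDOUT_CHROMS = ("chr4",)


def noiseless_config(seed: int = 0, n_genes: int = 30) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_genes=n_genes,
        n_chroms=2,
        mean_coverage=30.0,
        expression_dispersion=0.0,
        ase_skew=(0.5, 0.5),
        base_error_rate=0.0,
        editing_site_rate=0.0,
        indel_rate=0.0,
        duplication_rate=0.0,
    )


def clean_germline_config(seed: int = 0, n_genes: int = 200) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_genes=n_genes,
        n_chroms=4,
        mean_coverage=30.0,
        base_error_rate=0.005,
        expression_dispersion=0.2,
        snp_rate=0.002,
        indel_rate=2e-4,
        editing_site_rate=0.0,
        ase_skew=(0.3, 0.7),
        duplication_rate=0.02,
    )


def editing_rich_config(seed: int = 0, n_genes: int = 200) -> SimConfig:
    cfg = clean_germline_config(seed=seed, n_genes=n_genes)
    cfg.editing_site_rate = 1e-3
    cfg.editing_fraction = (0.2, 0.9)
    return cfg
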