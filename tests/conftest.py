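import numpy as np
import pytest

from splicecall.bench import Dataset
from splicecall.read_prep import AlignedRead, ReadSegment
from splicecall.scenarios import noiseless_config
from splicecall.sim import GenomeModel, SimConfig


@pytest.fixture(scope="session")
def noiseless_ds(tmp_path_factory) -> Dataset:
    """Small noiseless dataset shared across tests (error 0, ASE 0.5)."""
    out = tmp_path_factory.mktemp("noiseless_ds")
    return Dataset.simulate(noiseless_config(seed=1, n_genes=12), str(out))


@pytest.fixture(scope="session")
def stats_ds(tmp_path_factory) -> Dataset:
    """60-gene dataset with fixed ASE skew 0.6 for allele-fraction checks."""
    cfg = SimConfig(
        seed=3, n_genes=60, n_chroms=3, mean_coverage=30.0,
        expression_dispersion=0.2, ase_skew=(0.6, 0.6),
        base_error_rate=0.005, editing_site_rate=0.0, indel_rate=0.0,
        duplication_rate=0.02,
    )
    out = tmp_path_factory.mktemp("stats_ds")
    return Dataset.simulate(cfg, str(out))


def make_read(
    name="r1", chrom="chr1", pos=0, cigar=((("M", 10),)), seq=None,
    quals=None, mapq=60, **flags,
):
    cigar = list(cigar)
    qlen = sum(n for op, n in cigar if op in "MIS=X")
    if seq is None:
        seq = "A" * qlen
    if quals is None:
        quals = [30] * qlen
    return AlignedRead(
        name=name, chrom=chrom, pos=pos, cigar=cigar, seq=seq,
        base_quals=list(quals), mapq=mapq, **flags,
    )


def make_segment(**kw):
    kw.setdefault("parent_name", kw.get("name", "r1"))
    kw.setdefault("segment_index", 0)
    base = make_read(**{k: v for k, v in kw.items()
                        if k not in ("parent_name", "segment_index")})
    return ReadSegment(
        **{**base.__dict__, "parent_name": kw["parent_name"],
           "segment_index": kw["segment_index"]}
    )


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    return GenomeModel(sequences={"chr1": seq}, genes=[])
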