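"""A-to-I editing annotation and genotype x edit codon isoforms.

A-to-I RNA editing is read out by sequencers as A>G (or T>C on the reverse
strand) and is the classic source of false-positive germline calls from
RNA. This module (1) cross-tabulates evaluation outcomes by base change
and membership in an editing-site table, and (2) enumerates the mRNA
codons and protein isoforms a codon can produce when unphased DNA
genotypes and optional editing events combine — e.g. a heterozygous T/C
next to an A/G edit before a fixed C yields UAC (Tyr), UGC (Cys), CAC
(His) and CGC (Arg).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio.Data.CodonTable import standard_rna_table
from Bio.SeqUtils import seq3

from .evaluate import Outcome
from .formats import EditingSite

BASE_CHANGES = [
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
]  # 12 ordered ref>alt pairs

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def editing_crosstab(
    outcomes: Sequence[Outcome],
    editing_sites: Sequence[EditingSite],
) -> pd.DataFrame:
    """Count SNP outcomes by (outcome, base change, in editing table).

    Membership is an exact (chrom, pos) match against the editing table;
    the base change is reported separately, so both the position-only and
    the allele-aware views are recoverable. Indel records are excluded.
    """
    site_index = {(s.chrom, s.pos) for s in editing_sites}
    counts: Dict[Tuple[str, str, str], int] = {
        (o, ch, m): 0
        for o in ("TP", "FP", "FN")
        for ch in BASE_CHANGES
        for m in ("yes", "no")
    }
    for o in outcomes:
        if len(o.ref_allele) != 1 or len(o.alt_allele) != 1:
            continue
        change = f"{o.ref_allele}>{o.alt_allele}"
        if change not in BASE_CHANGES:
            continue
        member = "yes" if (o.chrom, o.pos) in site_index else "no"
        counts[(o.outcome, change, member)] += 1
    rows = [
        {"outcome": o, "base_change": ch, "in_editing_db": m, "count": n}
        for (o, ch, m), n in counts.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Codon isoform enumeration


@dataclass
class CodonPosition:
    """One genomic position of a codon context.

    ``genotype`` is an unphased pair of DNA bases or None (reference only);
    ``edit`` is the edited base an editing event can introduce, or None.
    Editing is per-molecule optional: both the edited and unedited base
    remain possible.
    """

    ref_base: str
    genotype: Optional[Tuple[str, str]] = None
    edit: Optional[str] = None

    def possibilities(self) -> Set[str]:
        bases = set(self.genotype) if self.genotype else {self.ref_base}
        if self.edit:
            bases.add(self.edit)
        for b in bases:
            if b not in "ACGT":
                raise ValueError(f"invalid base {b!r}")
        return bases


@dataclass
class CodonContext:
    """Three codomic positions in genomic order plus the gene strand."""

    positions: List[CodonPosition]
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.positions) != 3:
            raise ValueError("a codon context needs exactly 3 positions")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


def _translate_rna(codon_rna: str) -> str:
    """Three-letter amino acid name; '*' for a stop codon."""
    if codon_rna in standard_rna_table.stop_codons:
        return "*"
    aa1 = standard_rna_table.forward_table[codon_rna]
    return seq3(aa1)


def enumerate_isoforms(context: CodonContext) -> Set[Tuple[str, str]]:
    """All (mRNA codon, amino acid) pairs the context can produce.

    Unphased genotypes contribute every allele combination; editing events
    contribute both edited and unedited molecules. Minus-strand contexts
    are reverse-complemented before transcription, equivalent to
    enumerating the reverse-complemented plus-strand context.
    """
    per_pos = [p.possibilities() for p in context.positions]
    out: Set[Tuple[str, str]] = set()
    for combo in itertools.product(*per_pos):
        dna = "".join(combo)
        if context.strand == "-":
            dna = dna.translate(_COMPLEMENT)[::-1]
        rna = dna.replace("T", "U")
        out.add((rna, _translate_rna(rna)))
    return out


def context_from_dict(raw: Dict) -> CodonContext:
    """Build a CodonContext from a plain-JSON dict."""
    positions = []
    for p in raw["positions"]:
        gt = p.get("genotype")
        positions.append(
            CodonPosition(
                ref_base=p["ref_base"].upper(),
                genotype=tuple(b.upper() for b in gt) if gt else None,
                edit=p["edit"].upper() if p.get("edit") else None,
            )
        )
    return CodonContext(positions=positions, strand=raw.get("strand", "+"))
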