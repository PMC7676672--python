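"""Sequence-context proxy ratios for CpG-methylation-driven codon conversion.

Methylated cytosine in CpG dinucleotides deaminates to thymine over
evolutionary time, so CpG contexts are depleted where methylation acts. At the
weakly selected third codon position this predicts: NCG codons rarer than NCC
(second-position context), NCG rarer than NCA (the direct product of the
conversion), and codon junctions where a C-ending codon precedes a G-starting
codon (NC|G, a CpG) rarer than the NG|G counterpart. This module computes
those ratios from codon counts and spliced coding sequences, always carrying
the raw numerator/denominator counts so chi-square tests can run on counts
rather than ratios.

Junctions are evaluated on the spliced CDS (mRNA frame) within each gene:
intron-spanning junctions count as contiguous, and junctions never cross gene
boundaries. The focal codon must be internal and one of the 59 SCs; the
successor may be any internal codon (only its first base matters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .codon_metrics import CodonCountTable, SC_CODONS, SYNONYMOUS_FAMILIES
from .plastome_io import GeneModel

logger = logging.getLogger(__name__)

#: C-/G-ending synonymous pairs sharing their first two bases, per family
#: (six-codon families Ser/Leu/Arg restricted to their same-prefix pair)
NNG_NNC_PAIRS: dict[str, tuple[str, str]] = {
    "A": ("GCG", "GCC"),  # Ala
    "P": ("CCG", "CCC"),  # Pro
    "S": ("TCG", "TCC"),  # Ser
    "T": ("ACG", "ACC"),  # Thr
    "R": ("CGG", "CGC"),  # Arg
    "G": ("GGG", "GGC"),  # Gly
    "L": ("CTG", "CTC"),  # Leu
    "V": ("GTG", "GTC"),  # Val
}


@dataclass(frozen=True)
class RatioWithCounts:
    numerator: int
    denominator: int

    @property
    def ratio(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator


@dataclass
class ContextRatioSet:
    """All methylation-proxy ratios for one species, with raw counts."""

    second_pos_ratio: dict[str, RatioWithCounts]   # X -> NXG / NXC
    junction_ratio: dict[str, RatioWithCounts]     # X -> NC|X / NG|X
    ncg_nca: RatioWithCounts                       # NCG / NCA
    per_aa_gc: dict[str, RatioWithCounts]          # family -> NNG / NNC pair


def second_position_ratios(table: CodonCountTable) -> dict[str, RatioWithCounts]:
    """NXG/NXC ratios over eligible codons, for each second-position base X."""
    out = {}
    for x in "ACGT":
        num = sum(n for c, n in table.counts.items() if c[1] == x and c[2] == "G")
        den = sum(n for c, n in table.counts.items() if c[1] == x and c[2] == "C")
        if den == 0:
            logger.info("N%sG/N%sC undefined: zero denominator", x, x)
        out[x] = RatioWithCounts(num, den)
    return out


def junction_ratios(models: list[GeneModel]) -> dict[str, RatioWithCounts]:
    """NC|X / NG|X codon-junction ratios for each successor first base X.

    Scans consecutive codon pairs of each spliced CDS. The focal codon must be
    internal (neither first nor last) and one of the 59 SCs with third base C
    or G; the successor must be internal (any identity). Genes shorter than
    four codons contribute no pairs.
    """
    c_counts = {x: 0 for x in "ACGT"}
    g_counts = {x: 0 for x in "ACGT"}
    for model in models:
        if not model.passes_filter:
            continue
        codons = model.codons()
        if len(codons) < 4:
            logger.info("%s: too short for junction pairs", model.gene_name)
            continue
        # focal i in [1, n-3]: successor i+1 is internal (<= n-2)
        for i in range(1, len(codons) - 2):
            focal, nxt = codons[i], codons[i + 1]
            if focal not in SC_CODONS or nxt[0] not in "ACGT":
                continue
            if focal[2] == "C":
                c_counts[nxt[0]] += 1
            elif focal[2] == "G":
                g_counts[nxt[0]] += 1
    return {x: RatioWithCounts(c_counts[x], g_counts[x]) for x in "ACGT"}


def ncg_nca_ratio(table: CodonCountTable) -> RatioWithCounts:
    """NCG/NCA over eligible codons — the direct methylation-conversion proxy."""
    num = sum(n for c, n in table.counts.items() if c[1] == "C" and c[2] == "G")
    den = sum(n for c, n in table.counts.items() if c[1] == "C" and c[2] == "A")
    return RatioWithCounts(num, den)


def per_aa_g_to_c(table: CodonCountTable) -> dict[str, RatioWithCounts]:
    """Per-family NNG/NNC ratios for the eight families with a same-prefix pair."""
    out = {}
    for aa, (g_codon, c_codon) in NNG_NNC_PAIRS.items():
        assert g_codon in SYNONYMOUS_FAMILIES[aa] and c_codon in SYNONYMOUS_FAMILIES[aa]
        out[aa] = RatioWithCounts(table.counts[g_codon], table.counts[c_codon])
    return out


def context_ratio_set(table: CodonCountTable,
                      models: list[GeneModel]) -> ContextRatioSet:
    return ContextRatioSet(
        second_pos_ratio=second_position_ratios(table),
        junction_ratio=junction_ratios(models),
        ncg_nca=ncg_nca_ratio(table),
        per_aa_gc=per_aa_g_to_c(table),
    )
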