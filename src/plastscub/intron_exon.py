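"""SCUB resolved by intron class and by exon position.

Genes are grouped by their number of introns and, within a group, codons are
pooled by exon rank (1st, 2nd, 3rd exon of the mRNA, not genome order). A codon
that an intron interrupts belongs to the exon holding the majority of its
bases: split after the first nucleotide (phase 1|2) it goes to the downstream
exon, split after the second (phase 2|1) to the upstream exon. Both cases — and
the degenerate three-way split across a length-1 middle exon — reduce to "the
exon containing the codon's second nucleotide", which is the rule implemented.

Ratios are codon-pooled across the genes of a class by default (matching
chi-square testing on raw counts); a gene-averaged variant is available.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import accumulate

from .codon_metrics import SC_CODONS, count_codons
from .plastome_io import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class ExonCodonPartition:
    """Codons of one gene assigned to exon ranks, with split-codon bookkeeping."""

    gene_name: str
    per_exon_codons: list[list[str]]
    #: (codon index, split phase "1|2"/"2|1"/"1|1|1", assigned exon rank)
    assignment_log: list[tuple[int, str, int]] = field(default_factory=list)


@dataclass
class TerminalBaseRatio:
    """Third-position base counts over eligible codons and the pooled ratio."""

    n_genes: int
    nna: int
    nnt: int
    nnc: int
    nng: int

    @property
    def ratio(self) -> float | None:
        at = self.nna + self.nnt
        if at == 0:
            return None
        return (self.nnc + self.nng) / at


def partition_codons(model: GeneModel) -> ExonCodonPartition:
    """Assign each codon of a gene to an exon rank.

    Codon *i* occupies spliced-CDS positions [3i, 3i+3); its exon is the exon
    containing position 3i+1 (the second nucleotide). Split codons are
    recorded in the assignment log with their phase.
    """
    lengths = [len(e) for e in model.exons]
    if any(l == 0 for l in lengths):
        raise ValueError(f"{model.gene_name}: exon of length 0")
    boundaries = list(accumulate(lengths))  # cumulative exon ends

    def exon_of(pos: int) -> int:  # 0-based exon index
        return bisect_right(boundaries, pos)

    per_exon: list[list[str]] = [[] for _ in lengths]
    log: list[tuple[int, str, int]] = []
    for i, codon in enumerate(model.codons()):
        first, second, third = exon_of(3 * i), exon_of(3 * i + 1), exon_of(3 * i + 2)
        per_exon[second].append(codon)
        if first != third:
            if first == second:
                phase = "2|1"
            elif second == third:
                phase = "1|2"
            else:
                phase = "1|1|1"
            log.append((i, phase, second + 1))
    return ExonCodonPartition(model.gene_name, per_exon, log)


def scub_by_intron_class(
    models: list[GeneModel], gene_averaged: bool = False,
) -> dict[int, TerminalBaseRatio | float]:
    """NNC/G-to-NNA/T ratio per intron class.

    Genes are grouped by intron count; eligible codon counts are pooled per
    group and reduced to the four third-position base totals. With
    ``gene_averaged`` the per-gene ratios are averaged instead (genes whose
    ratio is undefined are skipped).
    """
    groups: dict[int, list[GeneModel]] = {}
    for m in models:
        if m.passes_filter:
            groups.setdefault(m.intron_count, []).append(m)
    out: dict[int, TerminalBaseRatio | float] = {}
    for k in sorted(groups):
        if gene_averaged:
            ratios = []
            for m in groups[k]:
                term = count_codons([m]).terminal_base_counts()
                at = term["A"] + term["T"]
                if at:
                    ratios.append((term["C"] + term["G"]) / at)
            if not ratios:
                logger.info("intron class %d: no gene with a defined ratio", k)
                continue
            out[k] = sum(ratios) / len(ratios)
        else:
            term = count_codons(groups[k]).terminal_base_counts()
            out[k] = TerminalBaseRatio(
                n_genes=len(groups[k]),
                nna=term["A"], nnt=term["T"], nnc=term["C"], nng=term["G"],
            )
    return out


def _eligible_indexed_codons(model: GeneModel) -> set[int]:
    """Indices of this gene's codons belonging to the 59-SC universe."""
    codons = model.codons()
    eligible = set()
    for i in range(1, len(codons) - 1):
        if codons[i] in SC_CODONS:
            eligible.add(i)
    return eligible


def scub_by_exon_position(
    models: list[GeneModel], intron_count: int,
) -> list[TerminalBaseRatio]:
    """NNC/G-to-NNA/T ratio per exon rank, over genes with a given intron count.

    Codons are pooled by mRNA exon rank across all genes of the class via
    :func:`partition_codons`; the start/stop codons, internal stops, internal
    ATG/TGG and ambiguous codons are excluded exactly as in the global counts
    but remain in the partition bookkeeping.
    """
    ranks = intron_count + 1
    counts = [{b: 0 for b in "ATCG"} for _ in range(ranks)]
    n_genes = 0
    for model in models:
        if not model.passes_filter or model.intron_count != intron_count:
            continue
        n_genes += 1
        eligible = _eligible_indexed_codons(model)
        part = partition_codons(model)
        index = 0
        for rank, codons in enumerate(part.per_exon_codons):
            for codon in codons:
                if index in eligible:
                    counts[rank][codon[2]] += 1
                index += 1
    out = []
    for rank in range(ranks):
        term = counts[rank]
        tbr = TerminalBaseRatio(
            n_genes=n_genes,
            nna=term["A"], nnt=term["T"], nnc=term["C"], nng=term["G"],
        )
        if tbr.ratio is None:
            logger.info("exon rank %d: ratio undefined (no A/T-ending codons)",
                        rank + 1)
        out.append(tbr)
    return out
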