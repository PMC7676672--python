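"""Codon counting and synonymous codon usage bias (SCUB) metrics.

The analysis universe is the set of 59 synonymous codons (SCs): the 64 triplets
minus the three stops (TAA, TAG, TGA), ATG (Met) and TGG (Trp), i.e. the codons
of the 18 amino acids encoded by at least two synonymous codons. Codon counts
pool the *internal* codons of every filtered gene: the first codon (start),
the final codon (stop), in-frame internal stops, internal ATG/TGG and any
codon containing an ambiguous base are excluded from the eligible tally but
tracked, so all exclusions are auditable.

On those counts the module computes:

* per-codon relative frequencies and RSCU (observed count x family size /
  family total, Sharp-Li definition);
* CAI as the geometric mean over eligible codon occurrences of
  relative-adaptiveness weights (w = RSCU / max family RSCU by default);
* per-amino-acid SCUB frequency, the ratio (NNC+NNG)/(NNA+NNT) within each of
  the 18 families, and its pooled counterpart across all SCs — the pipeline's
  core statistic;
* terminal-base frequencies NNA/NNT/NNC/NNG as fractions of the eligible
  denominator.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .plastome_io import GeneModel, PlastomeRecord, STOP_CODONS

logger = logging.getLogger(__name__)

_BASES = "TCAG"

#: all 64 triplets
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)

#: codon -> one-letter amino acid, standard genetic code (used by plastids)
CODON_TO_AA: dict[str, str] = dict(
    CodonTable.unambiguous_dna_by_id[1].forward_table
)

#: amino acid -> tuple of codons, for the 18 families with >= 2 synonymous codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)
SYNONYMOUS_FAMILIES = {
    aa: codons for aa, codons in SYNONYMOUS_FAMILIES.items() if len(codons) >= 2
}

#: the 59-SC universe
SC_CODONS: frozenset[str] = frozenset(
    c for codons in SYNONYMOUS_FAMILIES.values() for c in codons
)
assert len(SC_CODONS) == 59 and len(SYNONYMOUS_FAMILIES) == 18

AT_ENDING: frozenset[str] = frozenset(c for c in SC_CODONS if c[2] in "AT")
CG_ENDING: frozenset[str] = frozenset(c for c in SC_CODONS if c[2] in "CG")


@dataclass
class CodonCountTable:
    """Internal-codon counts over the 59-SC universe plus exclusion tallies."""

    counts: Counter = field(default_factory=Counter)
    excluded_tally: Counter = field(default_factory=Counter)

    @property
    def eligible_total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable(
            counts=self.counts + other.counts,
            excluded_tally=self.excluded_tally + other.excluded_tally,
        )

    def terminal_base_counts(self) -> dict[str, int]:
        """Eligible codon counts grouped by third-position base."""
        out = {b: 0 for b in "ATCG"}
        for codon, n in self.counts.items():
            out[codon[2]] += n
        return out


@dataclass
class ScubProfile:
    per_codon_freq: dict[str, float]
    rscu: dict[str, float | None]
    cai: float
    per_aa_ratio: dict[str, float | None]
    terminal_freq: dict[str, float]
    nncg_to_nnat: float


def count_codons(models: list[GeneModel]) -> CodonCountTable:
    """Pool eligible internal-codon counts across gene models.

    Exclusions, each tracked in ``excluded_tally``: the first codon (``start``
    if ATG else ``atypical_start``), the final codon (``stop`` if canonical
    else ``atypical_stop``), internal stops, internal ATG and TGG, and codons
    containing a base outside {A,C,G,T} (``ambiguous``).
    """
    table = CodonCountTable()
    for model in models:
        if not model.passes_filter:
            continue
        codons = model.codons()
        if len(codons) < 2:
            continue
        table.excluded_tally["start" if codons[0] == "ATG" else "atypical_start"] += 1
        table.excluded_tally[
            "stop" if codons[-1] in STOP_CODONS else "atypical_stop"] += 1
        for codon in codons[1:-1]:
            if classify_internal_codon(codon, table.excluded_tally):
                table.counts[codon] += 1
    return table


def classify_internal_codon(codon: str, excluded_tally: Counter) -> int:
    """Return 1 if the codon is eligible (one of the 59 SCs), tallying if not."""
    if any(b not in "ACGT" for b in codon):
        excluded_tally["ambiguous"] += 1
        return 0
    if codon in STOP_CODONS:
        excluded_tally["internal_stop"] += 1
        return 0
    if codon == "ATG" or codon == "TGG":
        excluded_tally[codon] += 1
        return 0
    return 1


def rscu(table: CodonCountTable) -> dict[str, float | None]:
    """Relative synonymous codon usage: count x family size / family total.

    Within each family the values sum to the family size (mean 1). A family
    with zero total reports ``None`` for its codons, not 0.
    """
    out: dict[str, float | None] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        family_total = sum(table.counts[c] for c in codons)
        for c in codons:
            out[c] = (
                None if family_total == 0
                else table.counts[c] * len(codons) / family_total
            )
    return out


def cai_weights(table: CodonCountTable, floor: float = 0.01) -> dict[str, float]:
    """Relative adaptiveness w = RSCU / max RSCU within each family.

    Zero weights (codon unused) are floored so the geometric mean is defined;
    each flooring is logged.
    """
    values = rscu(table)
    weights: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        family = {c: values[c] for c in codons if values[c] is not None}
        if not family:
            continue
        top = max(family.values())
        for c, v in family.items():
            w = v / top if top > 0 else floor
            if w <= 0:
                logger.info("CAI weight for %s floored to %g", c, floor)
                w = floor
            weights[c] = w
    return weights


def cai(table: CodonCountTable, weights: dict[str, float] | None = None,
        floor: float = 0.01) -> float:
    """Codon adaptation index: geometric mean of weights over eligible codons.

    With no external reference set, weights default to the table's own RSCU
    (w = RSCU / RSCUmax per family), so CAI measures internal consistency of
    usage. Always in (0, 1].
    """
    if weights is None:
        weights = cai_weights(table, floor=floor)
    log_sum = 0.0
    n = 0
    for codon, count in table.counts.items():
        if count == 0:
            continue
        w = weights.get(codon, floor)
        if w <= 0:
            logger.info("CAI weight for %s floored to %g", codon, floor)
            w = floor
        log_sum += count * math.log(w)
        n += count
    if n == 0:
        raise ValueError("CAI undefined on an empty codon table")
    return math.exp(log_sum / n)


def scub_profile(table: CodonCountTable,
                 include_internal_atg: bool = False) -> ScubProfile:
    """Full SCUB profile for one pooled codon table.

    ``include_internal_atg`` switches the frequency denominator from the
    59-SC total (default; terminal frequencies then sum to 1) to the looser
    reading that also counts internal ATG occurrences.
    """
    total = table.eligible_total
    if total == 0:
        raise ValueError("SCUB profile undefined on an empty codon table")
    denominator = total + (
        table.excluded_tally["ATG"] if include_internal_atg else 0
    )
    term_counts = table.terminal_base_counts()
    at = term_counts["A"] + term_counts["T"]
    cg = term_counts["C"] + term_counts["G"]
    per_aa: dict[str, float | None] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        num = sum(table.counts[c] for c in codons if c[2] in "CG")
        den = sum(table.counts[c] for c in codons if c[2] in "AT")
        if den == 0:
            logger.info("per-aa SCUB ratio undefined for %s (no NNA/NNT codons)", aa)
            per_aa[aa] = None
        else:
            per_aa[aa] = num / den
    return ScubProfile(
        per_codon_freq={c: table.counts[c] / denominator for c in sorted(SC_CODONS)},
        rscu=rscu(table),
        cai=cai(table),
        per_aa_ratio=per_aa,
        terminal_freq={b: term_counts[b] / denominator for b in "ATCG"},
        nncg_to_nnat=cg / at if at else float("inf"),
    )


def extreme_rscu(values: dict[str, float | None]) -> tuple[tuple[str, float], tuple[str, float]]:
    """(codon, value) pairs attaining the min and max RSCU over the 59 SCs.

    Exact ties report the lexicographically smallest codon.
    """
    defined = sorted((c, v) for c, v in values.items() if v is not None)
    lo = min(defined, key=lambda cv: (cv[1], cv[0]))
    hi = min(defined, key=lambda cv: (-cv[1], cv[0]))
    return lo, hi


def gc_vs_at_genomic(record: PlastomeRecord, models: list[GeneModel],
                     include_internal_atg: bool = False) -> dict[str, float]:
    """Base-composition GC/AT ratios for genome, gene bodies and third positions.

    Lets the third-position NNC/G-to-NNA/T ratio be compared against the raw
    nucleotide composition of the gene bodies and of the whole genomic
    sequence.
    """
    def gc_at(seq: str) -> float:
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        return gc / at if at else float("inf")

    gene_body = "".join(m.spliced_cds for m in models if m.passes_filter)
    table = count_codons(models)
    term = table.terminal_base_counts()
    at3 = term["A"] + term["T"]
    return {
        "genome_gc_at": gc_at(record.sequence),
        "gene_body_gc_at": gc_at(gene_body),
        "nncg_to_nnat": (term["C"] + term["G"]) / at3 if at3 else float("inf"),
    }
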