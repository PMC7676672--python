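"""Reading and writing annotated plastome records.

Chloroplast genomes arrive as GenBank flat files whose CDS features carry
``join(...)``/``complement(...)`` compound locations describing exon structure.
This module parses those records into :class:`GeneModel` objects — one per
annotated protein-coding feature — applying the gene filters used throughout
the pipeline: pseudogenes are dropped, spliced lengths must be a multiple of
three, and start/stop codons are classified as typical or atypical.

Coordinates are 0-based half-open internally; the GenBank 1-based inclusive
convention exists only at the file boundary. Inverted-repeat duplicate genes
are *not* deduplicated: every annotated non-pseudo CDS feature counts as a
separate gene. Trans-spliced genes (e.g. rps12) are processed exactly as their
location joins state.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonSegment:
    """One exon in genome coordinates (0-based half-open), ranked 5'->3' in mRNA."""

    start: int
    end: int
    strand: int  # +1 or -1
    rank: int    # 1-based position in the mRNA

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CdsFeatureDescriptor:
    """Raw CDS feature as annotated: location parts in mRNA order, plus flags."""

    gene_name: str
    parts: tuple[tuple[int, int, int], ...]  # (start, end, strand) in mRNA order
    pseudo: bool = False


@dataclass
class PlastomeRecord:
    accession: str
    organism: str
    sequence: str
    circular: bool
    features: list[CdsFeatureDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")


@dataclass
class GeneModel:
    """One protein-coding gene: exon structure plus the spliced coding sequence."""

    gene_name: str
    strand: int
    exons: list[ExonSegment]
    spliced_cds: str
    passes_filter: bool
    has_ambiguous: bool = False
    start_class: str | None = None            # "typical_ATG" or "atypical:XXX"
    stop_class: str | None = None             # "TAA"/"TAG"/"TGA" or "atypical:XXX"
    internal_stop_count: int = 0
    internal_stop_identities: Counter = field(default_factory=Counter)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    def codons(self) -> list[str]:
        return [self.spliced_cds[i:i + 3] for i in range(0, len(self.spliced_cds), 3)]


@dataclass(frozen=True)
class Rejection:
    accession: str
    gene_name: str
    reason: str


@dataclass
class GeneStructureSummary:
    intron_class_counts: dict[int, int]
    total: int
    start_codon_tally: Counter
    stop_codon_tally: Counter
    internal_stop_tally: Counter


# ---------------------------------------------------------------------------
# GenBank reading
# ---------------------------------------------------------------------------

def _feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return "unnamed"


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Parse a GenBank flat file into a :class:`PlastomeRecord`.

    All CDS features are captured (pseudo-flagged ones marked, not dropped);
    compound-location parts are stored in mRNA 5'->3' order as Biopython
    normalises them. A record with no CDS features yields a warning, not an
    error.
    """
    path = Path(path)
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises several parser error types
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc

    features = []
    for feat in seqrec.features:
        if feat.type != "CDS":
            continue
        parts = tuple(
            (int(p.start), int(p.end), int(p.strand or 1)) for p in feat.location.parts
        )
        features.append(
            CdsFeatureDescriptor(
                gene_name=_feature_name(feat),
                parts=parts,
                pseudo="pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers,
            )
        )
    if not features:
        warnings.warn(f"{path}: no CDS features found", stacklevel=2)

    return PlastomeRecord(
        accession=seqrec.id,
        organism=seqrec.annotations.get("organism", "unknown"),
        sequence=str(seqrec.seq).upper(),
        circular=seqrec.annotations.get("topology", "linear") == "circular",
        features=features,
    )


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    """Write a record back to GenBank flat-file format (round-trip safe)."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession.split(".")[0][:16],
        description=f"{record.organism} chloroplast genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.organism,
        },
    )
    for feat in record.features:
        locs = [SimpleLocation(s, e, strand) for s, e, strand in feat.parts]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [feat.gene_name]}
        if feat.pseudo:
            qualifiers["pseudo"] = [None]
        seqrec.features.append(SeqFeature(location, type="CDS", qualifiers=qualifiers))
    SeqIO.write(seqrec, str(path), "genbank")


def export_concatenated_cds(models: list[GeneModel], path: str | Path,
                            identifier: str = "concatenated_cds") -> None:
    """Write the concatenation of all filtered CDS as a single FASTA sequence."""
    combined = "".join(m.spliced_cds for m in models if m.passes_filter)
    SeqIO.write(
        SeqRecord(Seq(combined), id=identifier, description=""), str(path), "fasta"
    )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _extract_spliced(sequence: str, parts) -> str:
    chunks = []
    for start, end, strand in parts:
        sub = sequence[start:end]
        chunks.append(reverse_complement(sub) if strand == -1 else sub)
    return "".join(chunks)


def build_gene_models(
    record: PlastomeRecord,
    rejection_log: list[Rejection] | None = None,
) -> list[GeneModel]:
    """Build one :class:`GeneModel` per non-pseudo CDS feature.

    Features failing the length-multiple-of-three filter are returned with
    ``passes_filter=False``; pseudo features and features with out-of-range
    coordinates are skipped. Every excluded feature is appended to
    ``rejection_log`` with its reason.
    """
    models: list[GeneModel] = []
    n = len(record.sequence)

    def reject(name: str, reason: str) -> None:
        if rejection_log is not None:
            rejection_log.append(Rejection(record.accession, name, reason))

    for feat in record.features:
        if feat.pseudo:
            reject(feat.gene_name, "pseudo flag")
            continue
        if any(not (0 <= s < e <= n) for s, e, _ in feat.parts):
            reject(feat.gene_name, "coordinates invalid")
            warnings.warn(
                f"{record.accession}:{feat.gene_name}: exon coordinates out of "
                f"range, model skipped", stacklevel=2)
            continue

        exons = [
            ExonSegment(start=s, end=e, strand=st, rank=i + 1)
            for i, (s, e, st) in enumerate(feat.parts)
        ]
        spliced = _extract_spliced(record.sequence, feat.parts)
        ok = len(spliced) % 3 == 0
        if not ok:
            reject(feat.gene_name, "length not divisible by 3")
        model = GeneModel(
            gene_name=feat.gene_name,
            strand=feat.parts[0][2],
            exons=exons,
            spliced_cds=spliced,
            passes_filter=ok,
            has_ambiguous="N" in spliced,
        )
        if ok and len(spliced) >= 6:
            start_class, stop_class, n_internal, identities = classify_termini(model)
            model.start_class = start_class
            model.stop_class = stop_class
            model.internal_stop_count = n_internal
            model.internal_stop_identities = identities
        models.append(model)
    return models


def classify_termini(model: GeneModel) -> tuple[str, str, int, Counter]:
    """Classify the first and last codons and count in-frame internal stops.

    The first triplet is ``typical_ATG`` or ``atypical:<triplet>``; the final
    triplet is its own label if in {TAA, TAG, TGA}, otherwise
    ``atypical:<triplet>``. Internal stops are in-frame stop triplets strictly
    between the first and last codon.
    """
    cds = model.spliced_cds
    if len(cds) < 6:
        raise ValueError(
            f"{model.gene_name}: spliced CDS shorter than two codons has no interior")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    start_class = "typical_ATG" if codons[0] == "ATG" else f"atypical:{codons[0]}"
    stop_class = codons[-1] if codons[-1] in STOP_CODONS else f"atypical:{codons[-1]}"
    internal = Counter(c for c in codons[1:-1] if c in STOP_CODONS)
    return start_class, stop_class, sum(internal.values()), internal


def summarize_structure(models: list[GeneModel]) -> GeneStructureSummary:
    """Tally intron classes and start/stop/internal-stop codon usage.

    Only models passing the filter are counted. An empty list yields a summary
    of zeros.
    """
    kept = [m for m in models if m.passes_filter]
    intron_classes = Counter(m.intron_count for m in kept)
    start_tally: Counter = Counter()
    stop_tally: Counter = Counter()
    internal_tally: Counter = Counter()
    for m in kept:
        start_tally[m.spliced_cds[:3]] += 1
        stop_tally[m.spliced_cds[-3:]] += 1
        internal_tally.update(m.internal_stop_identities)
    return GeneStructureSummary(
        intron_class_counts=dict(sorted(intron_classes.items())),
        total=len(kept),
        start_codon_tally=start_tally,
        stop_codon_tally=stop_tally,
        internal_stop_tally=internal_tally,
    )


def write_rejection_log(rejections: list[Rejection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tgene\treason\n")
        for r in rejections:
            fh.write(f"{r.accession}\t{r.gene_name}\t{r.reason}\n")
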