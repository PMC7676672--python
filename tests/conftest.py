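from collections import Counter

import pytest

from plastscub.codon_metrics import CodonCountTable
from plastscub.plastome_io import (
    ExonSegment,
    GeneModel,
    PlastomeRecord,
    STOP_CODONS,
    classify_termini,
)


def make_gene(seq: str, exon_lengths: list[int] | None = None,
              name: str = "toy", strand: int = 1) -> GeneModel:
    """Build a GeneModel directly from a spliced CDS, with synthetic coordinates."""
    seq = seq.replace(" ", "").upper()
    if exon_lengths is None:
        exon_lengths = [len(seq)]
    assert sum(exon_lengths) == len(seq)
    exons, pos = [], 0
    for rank, length in enumerate(exon_lengths, start=1):
        exons.append(ExonSegment(start=pos, end=pos + length, strand=strand,
                                 rank=rank))
        pos += length + 10  # pretend introns of 10 nt
    model = GeneModel(
        gene_name=name, strand=strand, exons=exons, spliced_cds=seq,
        passes_filter=len(seq) % 3 == 0, has_ambiguous="N" in seq,
    )
    if model.passes_filter and len(seq) >= 6:
        (model.start_class, model.stop_class,
         model.internal_stop_count, model.internal_stop_identities
         ) = classify_termini(model)
    return model


def make_table(counts: dict[str, int]) -> CodonCountTable:
    return CodonCountTable(counts=Counter(counts))


def genbank_text(seq: str, locations: list[str], locus: str = "TOY1",
                 organism: str = "toy organism", topology: str = "circular",
                 qualifiers: list[str] | None = None) -> str:
    """Handcraft a GenBank flat file with the given raw CDS location strings."""
    lines = [
        f"LOCUS       {locus:<16}{len(seq):>12} bp    DNA     {topology:<8} UNK "
        "01-JAN-1980",
        "DEFINITION  toy.",
        f"ACCESSION   {locus}",
        f"VERSION     {locus}",
        "KEYWORDS    .",
        "SOURCE      .",
        f"  ORGANISM  {organism}",
        "            .",
        "FEATURES             Location/Qualifiers",
    ]
    for i, loc in enumerate(locations):
        lines.append(f"     CDS             {loc}")
        lines.append(f'                     /gene="g{i + 1}"')
        for q in qualifiers or []:
            lines.append(f"                     {q}")
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60].lower()
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_gb(tmp_path):
    def _write(text: str, name: str = "toy.gb"):
        path = tmp_path / name
        path.write_text(text)
        return path
    return _write
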