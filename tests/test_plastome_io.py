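"""GenBank parsing, gene-model construction and terminus classification."""

import pytest

from plastscub import (
    build_gene_models,
    classify_termini,
    read_genbank,
    summarize_structure,
    write_genbank,
)
from plastscub.plastome_io import Rejection, reverse_complement
from plastscub.synthetic import SyntheticTruth, generate_record

from conftest import genbank_text, make_gene


class TestReadGenbank:
    def test_minimal_single_cds(self, write_gb):
        path = write_gb(genbank_text("ATGTAAGCTAGCATGCATGCATGCATGCAT", ["1..6"]))
        rec = read_genbank(path)
        assert rec.accession == "TOY1"
        assert rec.organism == "toy organism"
        assert rec.circular
        assert len(rec.features) == 1
        assert rec.features[0].parts == ((0, 6, 1),)

    def test_join_location_keeps_part_order(self, write_gb):
        path = write_gb(genbank_text("ATGTAAGCTAGCATGCATGCATGCATGCAT",
                                     ["join(1..4,10..17)"]))
        rec = read_genbank(path)
        assert rec.features[0].parts == ((0, 4, 1), (9, 17, 1))

    def test_complement_join_reverses_mrna_rank_order(self, write_gb):
        seq = "ATGTAAGCTAGCATGCATGCATGCATGCAT"
        path = write_gb(genbank_text(seq, ["complement(join(2..5,11..18))"]))
        rec = read_genbank(path)
        # mRNA rank order is the reverse of genome order on the minus strand
        assert rec.features[0].parts == ((10, 18, -1), (1, 5, -1))
        models = build_gene_models(rec)
        expected = reverse_complement(seq[10:18]) + reverse_complement(seq[1:5])
        assert models[0].spliced_cds == expected

    def test_no_cds_warns_not_errors(self, write_gb):
        path = write_gb(genbank_text("ATGTAA", []))
        with pytest.warns(UserWarning, match="no CDS"):
            rec = read_genbank(path)
        assert rec.features == []

    def test_malformed_file_raises(self, tmp_path):
        path = tmp_path / "bad.gb"
        path.write_text("this is not genbank\n")
        with pytest.raises(ValueError, match="malformed"):
            read_genbank(path)

    def test_pseudo_flag_captured(self, write_gb):
        path = write_gb(genbank_text("ATGTAAGCTAGC", ["1..6"],
                                     qualifiers=["/pseudo"]))
        rec = read_genbank(path)
        assert rec.features[0].pseudo


class TestBuildGeneModels:
    def test_plus_strand_intronless(self, write_gb):
        path = write_gb(genbank_text("ATGTAACCCCCC", ["1..6"]))
        models = build_gene_models(read_genbank(path))
        assert models[0].spliced_cds == "ATGTAA"
        assert models[0].intron_count == 0

    def test_join_lengths_and_intron_count(self, write_gb):
        path = write_gb(genbank_text("ATGTAAGCTAGCATGCATGCATGCATGCAT",
                                     ["join(1..4,10..17)"]))
        models = build_gene_models(read_genbank(path))
        assert len(models[0].spliced_cds) == 12
        assert models[0].intron_count == 1

    def test_minus_strand_single_exon_reverse_complement(self, write_gb):
        # genome slice TTACAT read on the minus strand is ATGTAA
        path = write_gb(genbank_text("TTACATCCCCCC", ["complement(1..6)"]))
        models = build_gene_models(read_genbank(path))
        assert models[0].spliced_cds == "ATGTAA"

    def test_length_filter_and_rejection_log(self, write_gb):
        path = write_gb(genbank_text("ATGTAAGCTAGC", ["1..6", "1..7"]))
        log: list[Rejection] = []
        models = build_gene_models(read_genbank(path), rejection_log=log)
        assert [m.passes_filter for m in models] == [True, False]
        assert log[0].reason == "length not divisible by 3"

    def test_pseudo_flag_rejected(self, write_gb):
        text = genbank_text("ATGTAAGCTAGC", ["1..6"], qualifiers=["/pseudo"])
        log: list[Rejection] = []
        models = build_gene_models(read_genbank(write_gb(text)), rejection_log=log)
        assert models == []
        assert log[0].reason == "pseudo flag"

    def test_out_of_range_coordinates_rejected(self, write_gb):
        text = genbank_text("ATGTAAGCTAGC", ["1..50"])
        log: list[Rejection] = []
        with pytest.warns(UserWarning, match="out of range"):
            models = build_gene_models(read_genbank(write_gb(text)),
                                       rejection_log=log)
        assert models == []
        assert log[0].reason == "coordinates invalid"

    def test_ambiguous_base_retained_but_flagged(self, write_gb):
        path = write_gb(genbank_text("ATGNNNTAACCC", ["1..9"]))
        models = build_gene_models(read_genbank(path))
        assert models[0].passes_filter and models[0].has_ambiguous

    def test_spliced_length_equals_sum_of_exons(self, write_gb):
        path = write_gb(genbank_text("ATGTAAGCTAGCATGCATGCATGCATGCAT",
                                     ["join(1..4,10..17)", "complement(2..7)"]))
        for m in build_gene_models(read_genbank(path)):
            assert len(m.spliced_cds) == sum(len(e) for e in m.exons)
            assert [e.rank for e in m.exons] == list(range(1, len(m.exons) + 1))


class TestClassifyTermini:
    @pytest.mark.parametrize("seq,start,stop,n_internal", [
        ("ATGGCTTAA", "typical_ATG", "TAA", 0),
        ("ACGGCTTGA", "atypical:ACG", "TGA", 0),
        ("ATGTAAGCTTAG", "typical_ATG", "TAG", 1),
        ("ATGGCTGCA", "typical_ATG", "atypical:GCA", 0),
    ])
    def test_examples(self, seq, start, stop, n_internal):
        got = classify_termini(make_gene(seq))
        assert got[:3] == (start, stop, n_internal)

    def test_internal_stop_identity_recorded(self):
        _, _, n, identities = classify_termini(make_gene("ATGTAAGCTTAG"))
        assert n == 1 and identities == {"TAA": 1}

    def test_too_short_for_interior_raises(self):
        with pytest.raises(ValueError, match="interior"):
            classify_termini(make_gene("ATG"))


class TestSummarizeStructure:
    def test_three_intronless_toys(self):
        models = [make_gene("ATGGCTTAA") for _ in range(3)]
        s = summarize_structure(models)
        assert s.intron_class_counts == {0: 3}
        assert s.total == 3
        assert s.start_codon_tally == {"ATG": 3}
        assert s.stop_codon_tally == {"TAA": 3}

    def test_empty_input_gives_zeros(self):
        s = summarize_structure([])
        assert s.total == 0 and s.intron_class_counts == {}

    def test_intron_class_counts_sum_to_total(self):
        models = [make_gene("ATGGCTTAA"),
                  make_gene("ATGGCTGCATAA", exon_lengths=[5, 7]),
                  make_gene("ATGGCTGCAGCTTAA", exon_lengths=[4, 4, 7])]
        s = summarize_structure(models)
        assert sum(s.intron_class_counts.values()) == s.total == 3
        assert s.intron_class_counts == {0: 1, 1: 1, 2: 1}

    def test_unfiltered_models_excluded(self):
        models = [make_gene("ATGGCTTAA"), make_gene("ATGGCTTAAC")]
        assert summarize_structure(models).total == 1


class TestRoundTrip:
    def test_synthetic_record_survives_write_read(self, tmp_path):
        truth = SyntheticTruth(
            seed=7, n_genes_by_intron_class={0: 5, 1: 3, 2: 2},
            mean_gene_len_codons=60, include_origin_spanning=True)
        record, _ = generate_record(truth)
        path = tmp_path / "syn.gb"
        write_genbank(record, path)
        reread = read_genbank(path)
        assert reread.sequence == record.sequence
        original = build_gene_models(record)
        recovered = build_gene_models(reread)
        assert len(original) == len(recovered)
        for a, b in zip(original, recovered):
            assert a.spliced_cds == b.spliced_cds
            assert [(e.start, e.end, e.strand, e.rank) for e in a.exons] == \
                   [(e.start, e.end, e.strand, e.rank) for e in b.exons]

    def test_origin_spanning_gene_splices_correctly(self):
        truth = SyntheticTruth(seed=11, n_genes_by_intron_class={0: 2},
                               mean_gene_len_codons=40,
                               include_origin_spanning=True)
        record, _ = generate_record(truth)
        wrap = [m for m in build_gene_models(record) if m.gene_name == "wrapA"][0]
        assert wrap.passes_filter
        assert wrap.spliced_cds.startswith("ATG") or \
            wrap.start_class.startswith("atypical")
        assert wrap.spliced_cds[-3:] in {"TAA", "TAG", "TGA"}
        # the two location parts straddle the origin
        assert wrap.exons[0].start > 0 and wrap.exons[1].start == 0
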