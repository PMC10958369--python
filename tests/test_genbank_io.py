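"""GenBank I/O: coordinate conventions, strand handling, genetic code."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Data import CodonTable

from mitocompare.genbank_io import (
    DEFAULT_CODE,
    GenBankParseError,
    GeneFeature,
    GeneticCode,
    MitoGenome,
    feature_sequence,
    normalize_gene_name,
    parse_genbank,
    read_fasta,
    reverse_complement,
    write_fasta,
    write_genbank,
)


def _toy_genome(seq="ATGCATGCATGC", circular=True, features=()):
    return MitoGenome(
        id="TOY", sequence=seq, circular=circular, features=list(features)
    )


class TestGeneticCode:
    def test_table5_is_complete_and_invertebrate(self):
        code = GeneticCode.from_table(5)
        assert len(code.codon_to_aa) == 64
        assert code.codon_to_aa["TGA"] == "W"
        assert code.codon_to_aa["ATA"] == "M"
        assert code.codon_to_aa["AGA"] == "S"
        assert code.codon_to_aa["AGG"] == "S"
        assert code.stop_codons == {"TAA", "TAG"}

    def test_matches_ncbi_table(self):
        ncbi = CodonTable.unambiguous_dna_by_id[5]
        code = GeneticCode.from_table(5)
        for codon, aa in ncbi.forward_table.items():
            assert code.translate_codon(codon) == aa

    def test_serine_family_has_eight_codons(self):
        fams = GeneticCode.from_table(5).synonymous_families()
        assert len(fams["S"]) == 8
        assert len(fams["L"]) == 6


class TestRoundTrip:
    def test_simulated_genome_round_trips_exactly(self, root_genome, tmp_path):
        """Writing and re-parsing recovers the generator's feature table."""
        path = tmp_path / "root.gb"
        write_genbank(root_genome, path)
        (back,) = parse_genbank(path)
        assert back.sequence == root_genome.sequence
        assert back.circular
        assert len(back.features) == 38  # 13 PCG + 22 tRNA + 2 rRNA + D-loop
        got = [(f.name, f.kind, f.start, f.end, f.strand, f.wraps_origin)
               for f in back.features]
        want = [(f.name, f.kind, f.start, f.end, f.strand, f.wraps_origin)
                for f in root_genome.features]
        assert got == want

    def test_origin_wrapping_feature_round_trips(self, tmp_path):
        L = 600
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=L))
        feat = GeneFeature("cox1", "PCG", L - 90, 30, "J", wraps_origin=True)
        genome = MitoGenome(id="WRAP", sequence=seq, circular=True,
                            features=[feat])
        path = tmp_path / "wrap.gb"
        write_genbank(genome, path)
        (back,) = parse_genbank(path)
        f = back.features[0]
        assert (f.start, f.end, f.wraps_origin) == (L - 90, 30, True)
        assert feature_sequence(back, f) == seq[L - 90:] + seq[:30]

    def test_wrap_on_linear_record_is_hard_error(self, tmp_path):
        with pytest.raises(GenBankParseError, match="linear"):
            MitoGenome(
                id="BAD", sequence="ACGT" * 100, circular=False,
                features=[GeneFeature("cox1", "PCG", 390, 12, "J",
                                      wraps_origin=True)],
            )


class TestFeatureSequence:
    def test_strand_n_is_reverse_complement(self):
        g = _toy_genome("AAATGCAAAAAA")
        feat = GeneFeature("trnW", "tRNA", 2, 6, "N")
        g.features.append(feat)
        assert feature_sequence(g, feat) == "GCAT"

    def test_strand_j_is_plain_slice(self):
        g = _toy_genome("AAATGCAAAAAA")
        feat = GeneFeature("trnW", "tRNA", 2, 6, "J")
        g.features.append(feat)
        assert feature_sequence(g, feat) == g.sequence[2:6]

    def test_wrapping_concatenates_around_origin(self):
        seq = "ACGTACGTACGT"
        feat = GeneFeature("trnW", "tRNA", 10, 3, "J", wraps_origin=True)
        g = MitoGenome(id="X", sequence=seq, circular=True, features=[feat])
        assert feature_sequence(g, feat) == seq[10:] + seq[:3]

    def test_strand_n_equals_revcomp_of_strand_j(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        for start, end in [(0, 30), (17, 50), (100, 199)]:
            fj = GeneFeature("rrnS", "rRNA", start, end, "J")
            fn = GeneFeature("rrnL", "rRNA", start, end, "N")
            g = MitoGenome(id="X", sequence=seq, circular=True,
                           features=[fj, fn])
            assert feature_sequence(g, fn) == reverse_complement(
                feature_sequence(g, fj)
            )


class TestValidation:
    def test_ambiguity_codes_rejected(self):
        with pytest.raises(GenBankParseError, match="ambiguity"):
            MitoGenome(id="X", sequence="ACGTRY", circular=True)

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(GenBankParseError, match="outside"):
            MitoGenome(id="X", sequence="ACGTACGT", circular=True,
                       features=[GeneFeature("trnA", "tRNA", 2, 99, "J")])

    def test_short_pcg_rejected(self):
        with pytest.raises(GenBankParseError, match="codon"):
            MitoGenome(id="X", sequence="ACGTACGT", circular=True,
                       features=[GeneFeature("cox1", "PCG", 2, 4, "J")])


class TestNameNormalization:
    @pytest.mark.parametrize(
        "raw, want",
        [
            ("COX1", "cox1"), ("COI", "cox1"), ("cox1", "cox1"),
            ("CYTB", "cob"), ("cob", "cob"), ("ND4L", "nad4L"),
            ("tRNA-Ser(UCN)", "trnS2"), ("12S ribosomal RNA", "rrnS"),
            ("D-loop", "d_loop"), ("control region", "d_loop"),
        ],
    )
    def test_synonyms(self, raw, want):
        assert normalize_gene_name(raw) == want

    def test_unknown_name_is_none(self):
        assert normalize_gene_name("mystery_orf") is None


class TestFasta:
    def test_simple_write(self, tmp_path):
        path = tmp_path / "x.fasta"
        write_fasta({"a": "ACGT"}, path)
        assert path.read_text() == ">a\nACGT\n"

    def test_round_trip_random(self, tmp_path):
        rng = np.random.default_rng(5)
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 200))))
            for i in range(10)
        }
        path = tmp_path / "r.fasta"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs

    def test_duplicate_names_error(self, tmp_path):
        class Dup(dict):
            def __iter__(self):
                return iter(["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            write_fasta(Dup(a="ACGT"), tmp_path / "d.fasta")

    def test_empty_set_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="empty"):
            write_fasta({}, tmp_path / "e.fasta")
        assert (tmp_path / "e.fasta").read_text() == ""
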