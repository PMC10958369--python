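"""Supermatrix construction, saturation diagnostics, export."""

from __future__ import annotations

import numpy as np
import pytest

from mitocompare.alignment import MultipleAlignment
from mitocompare.genbank_io import GeneFeature, MitoGenome, reverse_complement
from mitocompare.supermatrix import (
    Supermatrix,
    build_supermatrix,
    export_for_inference,
    read_relaxed_phylip,
    saturation_stat,
    supermatrix_nj,
)
from mitocompare.trees import is_monophyletic


def _toy_genomes(n=3):
    """n genomes with two indel-free genes of 9 and 12 bp."""
    genes = {"cox1": "ATGAAATTT", "cox2": "ATGCCTGGTCAT"}
    out = []
    for i in range(n):
        full, feats, pos = [], [], 0
        for name, coding in genes.items():
            # introduce a taxon-specific synonymous-ish difference
            seq = list(coding)
            seq[4] = "ACGT"[(i + 1) % 4]
            feats.append(GeneFeature(name, "PCG", pos, pos + len(seq), "J"))
            full.append("".join(seq))
            pos += len(seq)
        out.append(MitoGenome(id=f"g{i}", sequence="".join(full),
                              circular=True, features=feats))
    return out


class TestBuild:
    def test_toy_widths(self):
        genomes = _toy_genomes()
        m123 = build_supermatrix(genomes, "PCG123", genes=("cox1", "cox2"))
        assert m123.alignment.length == 21
        m12 = build_supermatrix(genomes, "PCG12", genes=("cox1", "cox2"))
        assert m12.alignment.length == 14

    def test_partitions_tile(self, leaf_genomes):
        m = build_supermatrix(leaf_genomes)
        spans = sorted(m.partitions.values())
        assert spans[0][0] == 0
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 == s2
        assert spans[-1][1] == m.alignment.length
        assert len(m.partitions) == 13

    def test_pcg12_is_two_thirds(self, leaf_genomes):
        m123 = build_supermatrix(leaf_genomes, "PCG123")
        m12 = build_supermatrix(leaf_genomes, "PCG12")
        assert m12.alignment.length * 3 == m123.alignment.length * 2

    def test_duplicate_taxon_errors(self, leaf_genomes):
        with pytest.raises(ValueError, match="duplicate"):
            build_supermatrix([leaf_genomes[0]] * 3)

    def test_too_few_taxa_errors(self, leaf_genomes):
        with pytest.raises(ValueError, match="three"):
            build_supermatrix(leaf_genomes[:2])

    def test_missing_gene_becomes_gap_block(self, leaf_genomes):
        crippled = MitoGenome(
            id="crippled", sequence=leaf_genomes[0].sequence, circular=True,
            features=[f for f in leaf_genomes[0].features if f.name != "atp8"],
        )
        with pytest.warns(UserWarning, match="atp8"):
            m = build_supermatrix([crippled] + leaf_genomes[1:])
        start, end = m.partitions["atp8"]
        row = m.alignment.get("crippled")[start:end]
        assert set(row) == {"-"}


class TestSaturation:
    def test_low_divergence_transitions_rise_with_distance(self, leaf_genomes):
        m = build_supermatrix(leaf_genomes)
        out = saturation_stat(m)
        for pos in (1, 2, 3):
            assert out["slopes"][pos]["transition_slope"] > 0

    def test_random_sequences_hit_ts_tv_asymptote(self):
        """Mutating to randomness drives ts/tv to 4/8 = 0.5 (of the 12
        ordered mismatch pairs, 4 are transitions)."""
        rng = np.random.default_rng(90)
        seqs = ["".join(rng.choice(list("ACGT"), size=9000)) for _ in range(4)]
        aln = MultipleAlignment(
            ids=("a", "b", "c", "d"), seqs=tuple(seqs), alphabet="codon"
        )
        m = Supermatrix(alignment=aln, partitions={"x": (0, 9000)},
                        scheme="PCG123")
        table = saturation_stat(m)["table"]
        assert table["ts_tv"].mean() == pytest.approx(0.5, abs=0.05)

    def test_identical_taxa_give_zero_table(self, root_genome):
        seq = root_genome.sequence[:3000]
        aln = MultipleAlignment(
            ids=("a", "b", "c", "d"), seqs=(seq,) * 4, alphabet="codon"
        )
        m = Supermatrix(alignment=aln, partitions={"x": (0, 3000)},
                        scheme="PCG123")
        table = saturation_stat(m)["table"]
        assert (table["P"] == 0).all() and (table["Q"] == 0).all()

    def test_needs_all_positions(self, leaf_genomes):
        m = build_supermatrix(leaf_genomes, "PCG12")
        with pytest.raises(ValueError, match="codon positions"):
            saturation_stat(m)


class TestNJTree:
    def test_clade_structure_recovered(self, leaf_genomes):
        """t3/t4 are sisters in the simulation tree; the supermatrix NJ
        tree must recover that split."""
        m = build_supermatrix(leaf_genomes)
        tree = supermatrix_nj(m)
        assert sorted(tree.leaf_names()) == ["t1", "t2", "t3", "t4"]
        assert is_monophyletic(tree, ["t3", "t4"])


class TestExport:
    def test_phylip_header_and_round_trip(self, tmp_path):
        genomes = _toy_genomes()
        m = build_supermatrix(genomes, "PCG123", genes=("cox1", "cox2"))
        paths = export_for_inference(m, tmp_path)
        first_line = paths["phylip"].read_text().splitlines()[0]
        assert first_line == "3 21"
        back = read_relaxed_phylip(paths["phylip"])
        assert back.ids == m.alignment.ids
        assert back.seqs == m.alignment.seqs

    def test_partition_file_lists_all_genes(self, leaf_genomes, tmp_path):
        m = build_supermatrix(leaf_genomes)
        paths = export_for_inference(m, tmp_path)
        lines = paths["partitions"].read_text().splitlines()
        assert len(lines) == 13
        assert lines[0].startswith("DNA, atp6 = 1-")

    def test_nexus_charsets_mirror_partitions(self, leaf_genomes, tmp_path):
        m = build_supermatrix(leaf_genomes)
        paths = export_for_inference(m, tmp_path)
        text = paths["nexus"].read_text()
        for gene, (start, end) in m.partitions.items():
            assert f"CHARSET {gene} = {start + 1}-{end};" in text

    def test_export_is_byte_stable(self, leaf_genomes, tmp_path):
        m = build_supermatrix(leaf_genomes)
        p1 = export_for_inference(m, tmp_path / "a")
        p2 = export_for_inference(m, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
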