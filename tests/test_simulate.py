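"""The synthetic-data generator: contracts and truth-log consistency."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from mitocompare.codons import translate
from mitocompare.composition import composition
from mitocompare.diversity import junction_table
from mitocompare.genbank_io import gene_sequences, parse_genbank, write_genbank
from mitocompare.simulate import (
    SimulationConfig,
    evolve_along_tree,
    simulate_mitogenome,
    simulate_reads,
    write_fastq,
)


class TestRootGenome:
    def test_length_and_feature_count(self, root_genome):
        assert root_genome.length == 16176
        kinds = [f.kind for f in root_genome.features]
        assert kinds.count("PCG") == 13
        assert kinds.count("tRNA") == 22
        assert kinds.count("rRNA") == 2
        assert kinds.count("control_region") == 1

    def test_at_content_contract(self):
        for seed in (0, 1, 2):
            g = simulate_mitogenome(SimulationConfig(seed=seed, at_content=0.78))
            assert composition(g.sequence).at_content == pytest.approx(
                0.78, abs=0.01
            )

    def test_control_region_is_at_rich(self, root_genome):
        d = root_genome.get("d_loop")
        seq = root_genome.sequence[d.start: d.end]
        assert composition(seq).at_content == pytest.approx(0.893, abs=0.02)

    def test_published_junctions_reproduced(self, root_genome):
        jt = junction_table(root_genome)
        def rel(up, down):
            row = jt[(jt.upstream == up) & (jt.downstream == down)].iloc[0]
            return row["relation"], row["bp"]
        assert rel("atp8", "atp6") == ("overlap", 7)
        assert rel("trnW", "trnC") == ("overlap", 8)
        assert rel("trnE", "trnF") == ("spacer", 20)
        assert rel("trnS2", "nad1") == ("spacer", 16)

    def test_pcgs_are_valid_orfs(self, root_genome):
        """Start codon, no internal stop, in-frame under table 5."""
        from mitocompare.genbank_io import DEFAULT_CODE

        for name, seq in gene_sequences(root_genome).items():
            trimmed = seq[: len(seq) - len(seq) % 3]
            with warnings.catch_warnings():
                warnings.simplefilter("error")  # internal stops would warn
                prot = translate(trimmed)
            assert prot[0] in "MIVL", name  # table-5 start codons
            assert "*" not in prot[:-1], name

    def test_determinism_is_byte_exact(self):
        a = simulate_mitogenome(SimulationConfig(seed=33))
        b = simulate_mitogenome(SimulationConfig(seed=33))
        assert a.sequence == b.sequence
        assert a.features == b.features

    def test_seeds_differ(self):
        a = simulate_mitogenome(SimulationConfig(seed=1))
        b = simulate_mitogenome(SimulationConfig(seed=2))
        assert a.sequence != b.sequence

    def test_genbank_round_trip_recovers_layout(self, root_genome, tmp_path):
        write_genbank(root_genome, tmp_path / "g.gb")
        (back,) = parse_genbank(tmp_path / "g.gb")
        assert [f.name for f in back.features] == \
            [f.name for f in root_genome.features]

    def test_infeasible_layout_errors(self):
        with pytest.raises(ValueError, match="control region"):
            simulate_mitogenome(SimulationConfig(seed=0, genome_length=10_000))


class TestEvolution:
    def test_zero_branch_lengths_preserve_root(self, root_genome):
        leaves, log = evolve_along_tree(root_genome, "(x:0.0,y:0.0);", seed=4)
        assert leaves["x"].sequence == root_genome.sequence
        assert leaves["y"].sequence == root_genome.sequence
        assert (log["proposals"] == 0).all()

    def test_realized_events_match_expectation(self, root_genome):
        """Poisson proposal counts at t=0.1 over ~16 kb stay within 5
        sigma of t*L."""
        leaves, log = evolve_along_tree(
            root_genome, "(x:0.1,y:0.1);", kappa=2.0, omega=1.0, seed=5
        )
        L = root_genome.length
        for _, row in log.iterrows():
            lam = 0.1 * L
            assert abs(row["proposals"] - lam) < 5 * np.sqrt(lam)

    def test_omega_ordering_visible_in_truth_log(self, root_genome):
        """Accepted nonsyn/syn ratios order with omega."""
        ratios = {}
        for omega in (0.1, 1.0):
            _, log = evolve_along_tree(
                root_genome, "(x:0.15,y:0.15);", kappa=1.0, omega=omega, seed=6
            )
            nonsyn = sum(log[f"nonsyn_{g}"].sum() for g in
                         ("cox1", "cob", "nad5"))
            syn = sum(log[f"syn_{g}"].sum() for g in ("cox1", "cob", "nad5"))
            ratios[omega] = nonsyn / syn
        assert ratios[0.1] < ratios[1.0]

    def test_leaves_translate_cleanly(self, clade):
        """Stop-rejection keeps every evolved PCG free of internal stops."""
        _, leaves, _ = clade
        for genome in leaves.values():
            for name, seq in gene_sequences(genome).items():
                trimmed = seq[: len(seq) - len(seq) % 3]
                with warnings.catch_warnings():
                    warnings.simplefilter("error")
                    translate(trimmed)


class TestReads:
    def test_error_free_reads_are_substrings_with_wrap(self, root_genome):
        reads = simulate_reads(root_genome, n=200, length=120,
                               error_rate=0.0, seed=9)
        doubled = root_genome.sequence * 2
        assert all(seq in doubled for _, seq in reads)

    def test_some_reads_span_the_origin(self, root_genome):
        reads = simulate_reads(root_genome, n=2000, length=150,
                               error_rate=0.0, seed=10)
        linear = root_genome.sequence
        assert any(seq not in linear for _, seq in reads)

    def test_coverage_arithmetic(self, root_genome):
        n, length = 1000, 150
        reads = simulate_reads(root_genome, n=n, length=length,
                               error_rate=0.0, seed=11)
        cov = sum(len(s) for _, s in reads) / root_genome.length
        assert cov == pytest.approx(n * length / root_genome.length)

    def test_error_rate_realized(self, root_genome):
        reads = simulate_reads(root_genome, n=500, length=150,
                               error_rate=0.01, seed=12)
        doubled = root_genome.sequence * 2
        mismatches = 0
        # error-free placement is recoverable because we know the seed
        clean = simulate_reads(root_genome, n=500, length=150,
                               error_rate=0.0, seed=12)
        for (_, noisy), (_, ref) in zip(reads, clean):
            mismatches += sum(1 for x, y in zip(noisy, ref) if x != y)
        lam = 500 * 150 * 0.01
        assert abs(mismatches - lam) < 5 * np.sqrt(lam)

    def test_fastq_format(self, root_genome, tmp_path):
        reads = simulate_reads(root_genome, n=3, length=50, seed=13)
        path = tmp_path / "r.fastq"
        write_fastq(reads, path)
        from mitocompare.circularity import read_fastq

        assert read_fastq(path) == reads
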