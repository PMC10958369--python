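"""Sliding-window Pi and synteny accounting."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from mitocompare.alignment import MultipleAlignment
from mitocompare.diversity import (
    SyntenyRecord,
    compare_orders,
    gene_order,
    junction_table,
    sliding_pi,
    whole_alignment_pi,
)
from mitocompare.genbank_io import GeneFeature, MitoGenome


def _aln(*seqs: str) -> MultipleAlignment:
    return MultipleAlignment(
        ids=tuple(f"s{i}" for i in range(len(seqs))), seqs=seqs,
        alphabet="nucleotide",
    )


def brute_force_pi(seqs: list[str]) -> float | None:
    """Pooled pairwise-difference proportion, enumerated pair by pair."""
    diffs = compared = 0
    for a, b in combinations(seqs, 2):
        for x, y in zip(a, b):
            if x in "ACGT" and y in "ACGT":
                compared += 1
                diffs += x != y
    return diffs / compared if compared else None


class TestSlidingPi:
    def test_identical_sequences_zero_everywhere(self):
        aln = _aln("ACGTACGT", "ACGTACGT", "ACGTACGT")
        for w in sliding_pi(aln, 4, 2):
            assert w.pi == 0.0

    def test_fully_divergent_window_is_one(self):
        aln = _aln("AAAA", "CCCC")
        [w] = sliding_pi(aln, 4, 4)
        assert w.pi == 1.0

    def test_four_sequences_match_exhaustive_oracle(self):
        rng = np.random.default_rng(60)
        seqs = ["".join(rng.choice(list("ACGT-N"), size=50)) for _ in range(4)]
        aln = _aln(*seqs)
        [w] = sliding_pi(aln, 50, 50)
        assert w.pi == pytest.approx(brute_force_pi(seqs))

    def test_windows_match_oracle_per_window(self):
        rng = np.random.default_rng(61)
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(3)]
        aln = _aln(*seqs)
        for w in sliding_pi(aln, 20, 10):
            sub = [s[w.start: w.start + w.length] for s in seqs]
            assert w.pi == pytest.approx(brute_force_pi(sub))

    def test_aggregation_identity_when_step_equals_window(self):
        """sum(sites*pi)/sum(sites) over tiling windows == whole Pi,
        exactly, including gapped/ambiguous columns."""
        rng = np.random.default_rng(62)
        seqs = ["".join(rng.choice(list("ACGT-N"), size=97)) for _ in range(4)]
        aln = _aln(*seqs)
        windows = sliding_pi(aln, 10, 10)
        num = sum(w.sites * w.pi for w in windows if w.pi is not None)
        den = sum(w.sites for w in windows)
        assert num / den == pytest.approx(whole_alignment_pi(aln), abs=1e-12)

    def test_final_partial_window_retained_and_flagged(self):
        aln = _aln("ACGTACGTAC", "ACGTACGTAC")
        windows = sliding_pi(aln, 4, 4)
        assert windows[-1].partial
        assert windows[-1].start + windows[-1].length == 10

    def test_bad_window_or_step(self):
        aln = _aln("ACGT", "ACGT")
        with pytest.raises(ValueError):
            sliding_pi(aln, 0, 1)
        with pytest.raises(ValueError):
            sliding_pi(aln, 4, 0)
        with pytest.raises(ValueError, match="exceeds"):
            sliding_pi(aln, 5, 1)


def _toy_order(genes: list[tuple[str, str]]) -> SyntenyRecord:
    return SyntenyRecord(genome_id="toy", order=tuple(genes), junctions=())


def brute_adjacencies(genes: list[tuple[str, str]]) -> set:
    """Independent circular strand-aware adjacency builder."""
    flip = {"J": "N", "N": "J"}
    out = set()
    n = len(genes)
    for i in range(n):
        a, b = genes[i], genes[(i + 1) % n]
        rev = ((b[0], flip[b[1]]), (a[0], flip[a[1]]))
        out.add(min((a, b), rev))
    return out


class TestSynteny:
    def test_self_comparison_identical(self, root_genome):
        rec = gene_order(root_genome)
        res = compare_orders(rec, rec)
        assert res["identical"] and res["breakpoint_count"] == 0

    def test_two_gene_inversion_breakpoints(self):
        """Inverting (g2, g3) in a 5-gene circle breaks exactly the two
        flanking adjacencies (checked against a brute-force set oracle)."""
        orig = [("g1", "J"), ("g2", "J"), ("g3", "J"), ("g4", "J"), ("g5", "J")]
        inverted = [("g1", "J"), ("g3", "N"), ("g2", "N"), ("g4", "J"), ("g5", "J")]
        res = compare_orders(_toy_order(orig), _toy_order(inverted))
        want = len(brute_adjacencies(orig) - brute_adjacencies(inverted))
        assert want == 2
        assert res["breakpoint_count"] == want
        assert not res["identical"]

    def test_breakpoint_symmetry(self):
        rng = np.random.default_rng(70)
        genes = [(f"g{i}", "J") for i in range(8)]
        for _ in range(10):
            perm = list(genes)
            rng.shuffle(perm)
            a, b = _toy_order(genes), _toy_order(perm)
            assert compare_orders(a, b)["breakpoint_count"] == \
                compare_orders(b, a)["breakpoint_count"]

    def test_evolved_leaves_keep_root_order(self, clade):
        root, leaves, _ = clade
        ref = gene_order(root)
        for genome in leaves.values():
            assert compare_orders(ref, gene_order(genome))["identical"]


class TestJunctions:
    def _genome(self, feats, L=30, circular=True):
        return MitoGenome(id="J", sequence="A" * L, circular=circular,
                          features=feats)

    def test_overlap(self):
        g = self._genome([GeneFeature("trnA", "tRNA", 0, 10, "J"),
                          GeneFeature("trnC", "tRNA", 8, 20, "J")])
        jt = junction_table(g)
        row = jt.iloc[0]
        assert (row["relation"], row["bp"]) == ("overlap", 2)

    def test_spacer(self):
        g = self._genome([GeneFeature("trnA", "tRNA", 0, 10, "J"),
                          GeneFeature("trnC", "tRNA", 13, 20, "J")])
        row = junction_table(g).iloc[0]
        assert (row["relation"], row["bp"]) == ("spacer", 3)

    def test_circular_closure(self):
        g = self._genome([GeneFeature("trnA", "tRNA", 0, 10, "J"),
                          GeneFeature("trnC", "tRNA", 10, 25, "J")], L=30)
        jt = junction_table(g)
        last = jt.iloc[-1]
        assert (last["upstream"], last["downstream"]) == ("trnC", "trnA")
        assert (last["relation"], last["bp"]) == ("spacer", 5)

    def test_rotation_invariance(self, root_genome):
        """Junction lengths are unchanged by rotating the circular genome."""
        g = root_genome
        # rotate so that a mid-genome feature becomes the first one
        offset = g.features[17].start
        rotated_feats = []
        for f in g.features:
            ns = (f.start - offset) % g.length
            ne = (f.end - offset) % g.length
            if ne == 0:
                ne = g.length
            wraps = ns >= ne
            rotated_feats.append(
                GeneFeature(f.name, f.kind, ns, ne, f.strand,
                            wraps_origin=wraps)
            )
        rotated = MitoGenome(
            id="rot", sequence=g.sequence[offset:] + g.sequence[:offset],
            circular=True, features=rotated_feats,
        )
        orig = {(r.upstream, r.downstream): (r.relation, r.bp)
                for r in junction_table(g).itertuples()}
        rot = {(r.upstream, r.downstream): (r.relation, r.bp)
               for r in junction_table(rotated).itertuples()}
        assert orig == rot
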