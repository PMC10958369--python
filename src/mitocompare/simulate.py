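"""Synthetic annotated mitogenomes, divergent genome sets, and reads.

The generator emits the world the comparative analyses assume: a
circular ~16 kb genome with the standard 37-gene insect arrangement
(genes on both strands, the published small overlaps and spacers, an
A+T-rich control region with a tandem repeat), PCGs that are valid open
reading frames under the invertebrate mitochondrial code, sequence
divergence along a tree with a controllable transition/transversion
ratio (kappa) and per-gene dN/dS (omega), and uniformly sampled
substitution-error reads.

Selection is modelled by acceptance–rejection on top of a K80 proposal
process: nonsynonymous proposals are accepted with probability
min(1, omega) and synonymous proposals with min(1, 1/omega), so the
realized rate ratio equals omega on both sides of one. Proposals that
would create a stop codon in any reading frame crossing the site are
rejected outright. Every accepted event is logged per branch and per
gene, giving estimators an exact truth to be checked against.

Determinism: one seed fixes all outputs byte-exactly; each operation
draws from its own seed-derived substream, so adding an operation never
perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import dendropy

from .genbank_io import (
    DEFAULT_CODE,
    GeneFeature,
    GeneticCode,
    MitoGenome,
    reverse_complement,
    write_genbank,
)

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "default_insect_layout",
    "simulate_mitogenome",
    "evolve_along_tree",
    "simulate_clade",
    "simulate_reads",
    "write_fastq",
    "mutate_k80",
    "simulate_k80_pair",
]

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


def _substream(seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible stream for one named operation."""
    digest = sum(ord(c) * 131 ** i for i, c in enumerate(tag)) % (2**31 - 1)
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """One feature of the layout, with the gap to the next feature.

    ``gap_after`` > 0 is a spacer, < 0 an overlap. ``truncated_stop``
    marks PCGs whose stop is completed by polyadenylation in vivo; their
    trailing partial codon is left to the downstream gene.
    """

    name: str
    kind: str
    strand: str
    length: int
    gap_after: int = 0
    truncated_stop: bool = False
    tail: str | None = None  # explicit coding-sense tail (overlap feasibility)


def default_insect_layout() -> list[GeneSpec]:
    """The conserved dipteran 37-gene order with published junctions.

    Overlaps mirror the comparative set this package targets (e.g.
    atp8/atp6 7 bp, trnW/trnC 8 bp, spacers trnS2/nad1 16 bp and
    trnE/trnF 20 bp). The control region is sized at build time to reach
    the genome-length target.
    """
    G = GeneSpec
    # atp8's tail forces a valid atp6 start inside the 7 bp overlap:
    # ...GCA TAT TAA -> atp6 reads ATA | TTA | A.. in its own frame.
    return [
        G("trnI", "tRNA", "J", 66, 2),
        G("trnQ", "tRNA", "N", 69, 3),
        G("trnM", "tRNA", "J", 68, 0),
        G("nad2", "PCG", "J", 1023, -2),
        G("trnW", "tRNA", "J", 67, -8),
        G("trnC", "tRNA", "N", 64, 1),
        G("trnY", "tRNA", "N", 65, -2),
        G("cox1", "PCG", "J", 1536, -4),
        G("trnL2", "tRNA", "J", 66, 2),
        G("cox2", "PCG", "J", 687, 0),
        G("trnK", "tRNA", "J", 70, 1),
        G("trnD", "tRNA", "J", 67, 0),
        G("atp8", "PCG", "J", 159, -7, tail="GCATATTAA"),
        G("atp6", "PCG", "J", 678, -1),
        G("cox3", "PCG", "J", 786, 2),
        G("trnG", "tRNA", "J", 65, 0),
        G("nad3", "PCG", "J", 354, 1),
        G("trnA", "tRNA", "J", 64, -1),
        G("trnR", "tRNA", "J", 65, 2),
        G("trnN", "tRNA", "J", 66, 0),
        G("trnS1", "tRNA", "J", 67, 1),
        G("trnE", "tRNA", "J", 66, 20),
        G("trnF", "tRNA", "N", 65, 0),
        G("nad5", "PCG", "N", 1716, 1),
        G("trnH", "tRNA", "N", 65, 0),
        G("nad4", "PCG", "N", 1338, -1),
        G("nad4L", "PCG", "N", 288, 2),
        G("trnT", "tRNA", "J", 64, 0),
        G("trnP", "tRNA", "N", 66, 1),
        G("nad6", "PCG", "J", 524, -2, truncated_stop=True),
        G("cob", "PCG", "J", 1137, -2),
        G("trnS2", "tRNA", "J", 67, 16),
        G("nad1", "PCG", "N", 939, 1),
        G("trnL1", "tRNA", "N", 65, 0),
        G("rrnL", "rRNA", "N", 1326, 0),
        G("trnV", "tRNA", "N", 71, -2),
        G("rrnS", "rRNA", "N", 786, 0),
        G("d_loop", "control_region", "J", 0, 0),  # sized to target
    ]


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 16176
    at_content: float = 0.783
    control_region_at: float = 0.893
    layout: tuple[GeneSpec, ...] = field(
        default_factory=lambda: tuple(default_insect_layout())
    )
    tree: str = "(t1:0.05,t2:0.05,(t3:0.05,t4:0.05):0.03);"
    kappa: float = 2.0
    omega: Mapping[str, float] | float = 0.1
    read_length: int = 150
    read_count: int = 1000
    read_error_rate: float = 0.001
    genetic_code: int = 5

    def omega_for(self, gene: str) -> float:
        if isinstance(self.omega, Mapping):
            return float(self.omega.get(gene, 0.1))
        return float(self.omega)


def _base_probs(at: float) -> np.ndarray:
    """Base probabilities for an AT target, keeping fly-like A:T and C:G."""
    a, t, c, g = 0.401, 0.383, 0.126, 0.090
    pa, pt = at * a / (a + t), at * t / (a + t)
    pc, pg = (1 - at) * c / (c + g), (1 - at) * g / (c + g)
    return np.array([pa, pc, pg, pt])  # A C G T order


def _calibrated_codon_probs(target_at: float, code: GeneticCode) -> np.ndarray:
    """Base probabilities whose sense-codon-restricted sampler hits an AT
    target.

    Excluding stop codons (all A/T-rich under table 5) from codon
    sampling pulls realized AT below the nominal target; a short fixed
    point on the nominal AT compensates.
    """
    sense = [c for c in _ALL_CODONS if not code.is_stop(c)]
    alpha = target_at
    for _ in range(25):
        p = _base_probs(alpha)
        w = np.array([_codon_weight(c, p) for c in sense])
        at_frac = np.array(
            [sum(ch in "AT" for ch in c) / 3.0 for c in sense]
        )
        expected = float((w * at_frac).sum() / w.sum())
        alpha = min(0.99, max(0.01, alpha + (target_at - expected)))
    return _base_probs(alpha)


# ---------------------------------------------------------------------------
# Root genome construction
# ---------------------------------------------------------------------------

def _codon_weight(codon: str, probs: np.ndarray) -> float:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = 1.0
    for ch in codon:
        w *= probs[idx[ch]]
    return w


_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def _choose_codon(
    rng: np.random.Generator,
    candidates: Sequence[str],
    pattern: str,
    probs: np.ndarray,
) -> str | None:
    """Weighted draw among candidate codons matching a lock pattern
    (pattern chars: A/C/G/T fixed, '.' free)."""
    ok = [
        c for c in candidates
        if all(p == "." or p == ch for p, ch in zip(pattern, c))
    ]
    if not ok:
        return None
    w = np.array([_codon_weight(c, probs) for c in ok])
    return ok[int(rng.choice(len(ok), p=w / w.sum()))]


class LayoutError(ValueError):
    pass


def _place_layout(
    layout: Sequence[GeneSpec], genome_length: int
) -> list[tuple[GeneSpec, int, int]]:
    """Assign [start, end) spans; the control region absorbs the slack."""
    placed: list[tuple[GeneSpec, int, int]] = []
    pos = 0
    specs = list(layout)
    cr = [s for s in specs if s.kind == "control_region"]
    if len(cr) != 1 or specs[-1].kind != "control_region":
        raise LayoutError("layout must end with exactly one control region")
    for spec in specs[:-1]:
        start, end = pos, pos + spec.length
        placed.append((spec, start, end))
        pos = end + spec.gap_after
    cr_len = genome_length - pos
    if cr_len < 100:
        raise LayoutError(
            f"layout leaves {cr_len} bp for the control region; "
            "genome_length target too small"
        )
    placed.append((specs[-1], pos, pos + cr_len))
    if pos + cr_len != genome_length:
        raise LayoutError("layout does not close the circle")
    return placed


def _pcg_pattern(
    locked: np.ndarray, seq: np.ndarray, start: int, end: int, strand: str
) -> str:
    """Coding-sense lock pattern for a PCG span."""
    span = [
        seq[i].decode() if locked[i] else "." for i in range(start, end)
    ]
    if strand == "N":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", ".": "."}
        span = [comp[ch] for ch in reversed(span)]
    return "".join(span)


def simulate_mitogenome(
    config: SimulationConfig, out_genbank: str | Path | None = None
) -> MitoGenome:
    """Build the root genome: layout -> ORFs -> structural RNA filler.

    PCGs are generated first (lock-aware in overlap regions, so every
    complete codon is a sense codon and starts/stops are genuine), then
    tRNA/rRNA and the control region fill the remaining positions.
    """
    rng = _substream(config.seed, "root_genome")
    code = GeneticCode.from_table(config.genetic_code)
    placed = _place_layout(config.layout, config.genome_length)
    L = config.genome_length
    # the AT-rich control region is hotter than the rest; solve the gene
    # region's AT so the genome-wide content meets the target
    cr_len = next(e - s for sp, s, e in placed if sp.kind == "control_region")
    gene_at = (config.at_content * L - config.control_region_at * cr_len) / (
        L - cr_len
    )
    gene_at = min(0.99, max(0.01, gene_at))
    probs = _base_probs(gene_at)
    codon_probs = _calibrated_codon_probs(gene_at, code)
    cr_probs = _base_probs(config.control_region_at)
    seq = np.full(L, b"N", dtype="S1")
    locked = np.zeros(L, dtype=bool)

    sense = [c for c in _ALL_CODONS if not code.is_stop(c)]
    starts = sorted(code.start_codons & {"ATG", "ATA", "ATT", "ATC", "GTG", "TTG"})
    stops = sorted(code.stop_codons)

    def write_coding(spec: GeneSpec, start: int, end: int) -> None:
        n_complete = (end - start) // 3
        pattern = _pcg_pattern(locked, seq, start, end, spec.strand)
        codons: list[str] = []
        tail = spec.tail or ""
        n_tail = len(tail) // 3
        for ci in range(n_complete):
            pat = pattern[3 * ci: 3 * ci + 3]
            if ci >= n_complete - n_tail:
                codon = tail[3 * (ci - (n_complete - n_tail)):][:3]
                if any(p not in (".", ch) for p, ch in zip(pat, codon)):
                    raise LayoutError(f"{spec.name}: tail conflicts with locks")
            elif ci == 0:
                codon = _choose_codon(rng, starts, pat, codon_probs)
                if codon is None:  # locked head: any sense codon
                    codon = _choose_codon(rng, sense, pat, codon_probs)
            elif ci == n_complete - 1 and not spec.truncated_stop and not tail:
                codon = _choose_codon(rng, stops, pat, codon_probs)
                if codon is None:
                    codon = _choose_codon(rng, sense, pat, codon_probs)
            else:
                codon = _choose_codon(rng, sense, pat, codon_probs)
            if codon is None:
                raise LayoutError(
                    f"{spec.name}: codon {ci} infeasible under locks ({pat})"
                )
            codons.append(codon)
        coding = "".join(codons)
        forward = coding if spec.strand == "J" else reverse_complement(coding)
        # place complete codons; a truncated stop leaves its partial tail
        # to the downstream gene
        if spec.strand == "J":
            s0 = start
        else:
            s0 = end - 3 * n_complete
        for k, ch in enumerate(forward):
            pos = s0 + k
            if not locked[pos]:
                seq[pos] = ch.encode()
                locked[pos] = True

    # pass 1: PCGs in forward order
    for spec, start, end in placed:
        if spec.kind == "PCG":
            write_coding(spec, start, end)
    # pass 2: everything else fills unlocked positions
    for spec, start, end in placed:
        if spec.kind == "PCG":
            continue
        p = cr_probs if spec.kind == "control_region" else probs
        hole = [i for i in range(start, end) if not locked[i]]
        fill = rng.choice(_BASES, size=len(hole), p=p)
        for i, ch in zip(hole, fill):
            seq[i] = ch.encode()
            locked[i] = True
        if spec.kind == "control_region" and end - start > 200:
            # seeded tandem repeat: real D-loops carry these and they are
            # what makes control regions hard to align
            unit = "".join(rng.choice(_BASES, size=12, p=cr_probs))
            repeat = (unit * 8)[: min(96, (end - start) // 4)]
            mid = start + (end - start) // 2
            for k, ch in enumerate(repeat):
                seq[mid + k] = ch.encode()
    # leftover inter-gene spacer bases
    holes = np.where(~locked)[0]
    if len(holes):
        fill = rng.choice(_BASES, size=len(holes), p=probs)
        for i, ch in zip(holes, fill):
            seq[i] = ch.encode()

    features = [
        GeneFeature(
            name=spec.name, kind=spec.kind, start=start, end=end,
            strand=spec.strand,
        )
        for spec, start, end in placed
    ]
    genome = MitoGenome(
        id="SIM_ROOT",
        sequence=b"".join(seq).decode(),
        circular=True,
        features=features,
        source_taxon="Simulated fly",
    )
    if out_genbank is not None:
        write_genbank(genome, out_genbank)
    return genome


# ---------------------------------------------------------------------------
# Evolution along a tree
# ---------------------------------------------------------------------------

def _k80_propose(rng: np.random.Generator, base: str, kappa: float) -> str:
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][int(rng.integers(2))]


class _CodingMap:
    """Forward-position ownership and frame registry for a genome."""

    def __init__(self, genome: MitoGenome, code: GeneticCode):
        L = genome.length
        self.owner = np.full(L, -1, dtype=int)  # index into self.genes
        self.genes: list[GeneFeature] = []
        self.frames: dict[int, list[int]] = {}  # pos -> gene indices
        for feat in genome.features:
            if feat.kind != "PCG":
                continue
            gi = len(self.genes)
            self.genes.append(feat)
            span = list(range(feat.start, feat.end))
            n_complete = len(span) // 3
            coding_positions = (
                span[: 3 * n_complete] if feat.strand == "J"
                else span[len(span) - 3 * n_complete:]
            )
            for pos in coding_positions:
                self.frames.setdefault(pos, []).append(gi)
                if self.owner[pos] < 0:
                    self.owner[pos] = gi

    def codon_at(self, seq: list[str], gi: int, pos: int) -> tuple[int, str]:
        """(codon index, coding-sense codon) of gene gi covering pos."""
        feat = self.genes[gi]
        if feat.strand == "J":
            ci = (pos - feat.start) // 3
            s = feat.start + 3 * ci
            codon = "".join(seq[s: s + 3])
            return ci, codon
        # N strand: coding index counts from the forward end
        n_complete = (feat.end - feat.start) // 3
        first = feat.end - 3 * n_complete
        ci = (feat.end - 1 - pos) // 3
        e = feat.end - 3 * ci
        codon = reverse_complement("".join(seq[e - 3: e]))
        return ci, codon


def _evolve_branch(
    seq: list[str],
    cmap: _CodingMap,
    t: float,
    kappa: float,
    omega_for,
    code: GeneticCode,
    rng: np.random.Generator,
) -> dict:
    """Mutate ``seq`` in place along one branch; returns event counts."""
    L = len(seq)
    n_events = rng.poisson(t * L)
    positions = rng.integers(0, L, size=n_events)
    stats = {
        "proposals": int(n_events),
        "neutral_events": 0,
        "syn": {f.name: 0 for f in cmap.genes},
        "nonsyn": {f.name: 0 for f in cmap.genes},
    }
    for pos in positions:
        pos = int(pos)
        old = seq[pos]
        new = _k80_propose(rng, old, kappa)
        gi = cmap.owner[pos]
        if gi < 0:
            seq[pos] = new
            stats["neutral_events"] += 1
            continue
        # classify against the owner's frame
        _, codon_old = cmap.codon_at(seq, gi, pos)
        seq[pos] = new
        _, codon_new = cmap.codon_at(seq, gi, pos)
        rollback = False
        for fi in cmap.frames[pos]:
            _, c = cmap.codon_at(seq, fi, pos)
            if code.is_stop(c):
                rollback = True
                break
        if rollback:
            seq[pos] = old
            continue
        name = cmap.genes[gi].name
        omega = omega_for(name)
        if code.translate_codon(codon_new) == code.translate_codon(codon_old):
            if omega > 1.0 and rng.random() >= 1.0 / omega:
                seq[pos] = old
                continue
            stats["syn"][name] += 1
        else:
            if rng.random() >= min(1.0, omega):
                seq[pos] = old
                continue
            stats["nonsyn"][name] += 1
    return stats


def evolve_along_tree(
    root: MitoGenome,
    tree: str,
    *,
    kappa: float = 2.0,
    omega: Mapping[str, float] | float = 0.1,
    seed: int = 0,
    code: GeneticCode | None = None,
) -> tuple[dict[str, MitoGenome], pd.DataFrame]:
    """Evolve a root genome down a newick tree.

    Branch lengths are expected substitution proposals per site; the
    realized (accepted) events are logged per branch and per gene so
    estimators can be checked against exact truth. Returns the leaf
    genomes keyed by taxon label and the truth log.
    """
    code = code or GeneticCode.from_table(5)
    rng = _substream(seed, "evolve_tree")
    dtree = dendropy.Tree.get(data=tree, schema="newick")
    cmap = _CodingMap(root, code)
    omega_for = (
        (lambda g: float(omega.get(g, 0.1)))
        if isinstance(omega, Mapping) else (lambda g: float(omega))
    )
    log_rows: list[dict] = []
    leaves: dict[str, MitoGenome] = {}

    def recurse(node, seq: list[str]) -> None:
        for child in node.child_nodes():
            child_seq = list(seq)
            t = child.edge.length or 0.0
            label = (
                child.taxon.label if child.taxon is not None
                else f"node{id(child) % 10_000}"
            )
            stats = _evolve_branch(
                child_seq, cmap, t, kappa, omega_for, code, rng
            )
            row = {
                "branch_to": label,
                "length": t,
                "proposals": stats["proposals"],
                "neutral_events": stats["neutral_events"],
            }
            for g in stats["syn"]:
                row[f"syn_{g}"] = stats["syn"][g]
                row[f"nonsyn_{g}"] = stats["nonsyn"][g]
            log_rows.append(row)
            if child.is_leaf():
                taxon = child.taxon.label.replace(" ", "_")
                leaves[taxon] = MitoGenome(
                    id=taxon,
                    sequence="".join(child_seq),
                    circular=root.circular,
                    features=list(root.features),
                    source_taxon=taxon,
                )
            else:
                recurse(child, child_seq)

    recurse(dtree.seed_node, list(root.sequence))
    return leaves, pd.DataFrame(log_rows)


def simulate_clade(
    config: SimulationConfig,
) -> tuple[MitoGenome, dict[str, MitoGenome], pd.DataFrame]:
    """Root genome plus leaf genomes evolved along ``config.tree``."""
    root = simulate_mitogenome(config)
    leaves, log = evolve_along_tree(
        root,
        config.tree,
        kappa=config.kappa,
        omega=config.omega,
        seed=config.seed,
        code=GeneticCode.from_table(config.genetic_code),
    )
    return root, leaves, log


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: MitoGenome | str,
    n: int,
    length: int,
    error_rate: float = 0.001,
    seed: int = 0,
    circular: bool | None = None,
) -> list[tuple[str, str]]:
    """Uniform single-end reads with iid substitution errors."""
    seq = genome if isinstance(genome, str) else genome.sequence
    if circular is None:
        circular = genome.circular if isinstance(genome, MitoGenome) else True
    L = len(seq)
    if length > L:
        raise ValueError("read length exceeds genome length")
    rng = _substream(seed, "reads")
    doubled = seq + seq
    # starts are drawn in one batch so the error process is orthogonal:
    # the same seed places reads identically at any error rate
    starts = rng.integers(0, L if circular else L - length + 1, size=n)
    reads: list[tuple[str, str]] = []
    for i in range(n):
        start = int(starts[i])
        read = list(doubled[start: start + length])
        if error_rate > 0:
            hits = np.where(rng.random(length) < error_rate)[0]
            for h in hits:
                alt = [b for b in "ACGT" if b != read[h]]
                read[h] = alt[int(rng.integers(3))]
        reads.append((f"read_{i}", "".join(read)))
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Small K80 helpers (estimator-recovery harnesses)
# ---------------------------------------------------------------------------

def mutate_k80(
    seq: str, t: float, kappa: float, rng: np.random.Generator
) -> str:
    """Apply a K80 process at expected ``t`` events/site (Poisson)."""
    out = list(seq)
    n_events = rng.poisson(t * len(out))
    for pos in rng.integers(0, len(out), size=n_events):
        out[int(pos)] = _k80_propose(rng, out[int(pos)], kappa)
    return "".join(out)


def simulate_k80_pair(
    length: int, distance: float, kappa: float = 2.0, seed: int = 0
) -> tuple[str, str]:
    """Two sequences whose true evolutionary distance is ``distance``."""
    rng = _substream(seed, "k80_pair")
    anc = "".join(rng.choice(_BASES, size=length))
    a = mutate_k80(anc, distance / 2.0, kappa, rng)
    b = mutate_k80(anc, distance / 2.0, kappa, rng)
    return a, b
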