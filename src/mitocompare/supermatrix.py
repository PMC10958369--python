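"""Concatenated PCG supermatrices, saturation diagnostics, and NJ checks.

The 13 protein-coding genes are codon-aware aligned per gene and
concatenated in a fixed alphabetical order (atp6 ... nad6) recorded in
the partition map. Two position schemes are supported: PCG123 keeps all
codon positions, PCG12 drops every third column (third positions can be
saturated at deep timescales). Model-based tree inference is exported to
external tools (relaxed PHYLIP, NEXUS with charsets, RAxML-style
partitions); the NJ tree built here is an internal sanity check for
topology-level claims such as genus monophyly.

Substitution saturation is diagnosed per codon position by regressing
per-pair transition/transversion proportions on K2P distance: at low
divergence transitions grow linearly; saturation shows as a transition
plateau and an s/v ratio decaying toward the random-sequence asymptote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import GAP, MultipleAlignment, progressive_align
from .distances import k2p
from .genbank_io import (
    DEFAULT_CODE,
    GeneticCode,
    MitoGenome,
    PCG_NAMES,
    gene_sequences,
)
from .trees import DistanceMatrix, PhyloTree, is_monophyletic, nj_tree

__all__ = [
    "Supermatrix",
    "build_supermatrix",
    "saturation_stat",
    "supermatrix_nj",
    "export_for_inference",
    "read_relaxed_phylip",
]

GENE_ORDER: tuple[str, ...] = PCG_NAMES  # alphabetical canonical order


@dataclass(frozen=True)
class Supermatrix:
    alignment: MultipleAlignment
    partitions: Mapping[str, tuple[int, int]]  # gene -> [start, end) columns
    scheme: str  # PCG123 | PCG12

    def __post_init__(self) -> None:
        spans = sorted(self.partitions.values())
        pos = 0
        for start, end in spans:
            if start != pos or end < start:
                raise ValueError("partitions do not tile the matrix")
            pos = end
        if pos != self.alignment.length:
            raise ValueError("partitions do not cover the matrix")

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.alignment.ids

    def gene_block(self, gene: str) -> MultipleAlignment:
        start, end = self.partitions[gene]
        return MultipleAlignment(
            ids=self.alignment.ids,
            seqs=tuple(s[start:end] for s in self.alignment.seqs),
            alphabet=self.alignment.alphabet,
        )


def _drop_third_positions(seq: str) -> str:
    return "".join(ch for i, ch in enumerate(seq) if i % 3 != 2)


def build_supermatrix(
    genomes: Sequence[MitoGenome],
    scheme: str = "PCG123",
    *,
    genes: Sequence[str] = GENE_ORDER,
    code: GeneticCode = DEFAULT_CODE,
) -> Supermatrix:
    """Concatenated codon-aware alignment of the PCGs across genomes.

    A genome lacking a gene contributes an all-gap block for it (with a
    warning), so nearly complete mitogenomes can still be included.
    """
    if scheme not in ("PCG123", "PCG12"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if len(genomes) < 3:
        raise ValueError("a supermatrix needs at least three taxa")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon ids")
    blocks: dict[str, dict[str, str]] = {}
    widths: dict[str, int] = {}
    for gene in genes:
        have = {
            g.id: s for g in genomes
            for s in [gene_sequences(g, [gene]).get(gene)] if s
        }
        missing = [i for i in ids if i not in have]
        if missing:
            warnings.warn(
                f"{gene}: missing from {missing}; all-gap block inserted",
                stacklevel=2,
            )
        if len(have) < 2:
            warnings.warn(f"{gene}: fewer than two sequences; gene skipped",
                          stacklevel=2)
            continue
        aln = progressive_align(have, code=code)
        width = aln.length
        block = {tid: aln.get(tid) if tid in have else GAP * width for tid in ids}
        if scheme == "PCG12":
            block = {tid: _drop_third_positions(s) for tid, s in block.items()}
            width = len(next(iter(block.values())))
        blocks[gene] = block
        widths[gene] = width
    partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    for gene in genes:
        if gene not in blocks:
            continue
        partitions[gene] = (pos, pos + widths[gene])
        pos += widths[gene]
    seqs = tuple(
        "".join(blocks[gene][tid] for gene in genes if gene in blocks)
        for tid in ids
    )
    aln = MultipleAlignment(
        ids=tuple(ids), seqs=seqs,
        alphabet="codon" if scheme == "PCG123" else "nucleotide",
    )
    return Supermatrix(alignment=aln, partitions=partitions, scheme=scheme)


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

def saturation_stat(matrix: Supermatrix) -> dict:
    """Transition/transversion behaviour vs distance, per codon position.

    Returns a per-pair table (position, pair, P, Q, ts/tv, K2P distance)
    and per-position least-squares slopes of P and Q on distance. The
    verdict is left to the user: a positive transition slope without a
    plateau argues against saturation; an s/v ratio falling toward 0.5
    (the random-sequence limit under equal base use) indicates it.
    """
    if matrix.scheme != "PCG123":
        raise ValueError("saturation analysis needs all three codon positions")
    if len(matrix.taxa) < 4:
        raise ValueError("need at least four taxa")
    aln = matrix.alignment
    rows: list[dict] = []
    for pos in (1, 2, 3):
        sub = {
            tid: "".join(
                ch for i, ch in enumerate(aln.get(tid)) if i % 3 == pos - 1
            )
            for tid in matrix.taxa
        }
        for ta, tb in combinations(matrix.taxa, 2):
            res = k2p(sub[ta], sub[tb])
            rows.append(
                {
                    "position": pos,
                    "taxon_i": ta,
                    "taxon_j": tb,
                    "P": res.P,
                    "Q": res.Q,
                    "ts_tv": res.P / res.Q if res.Q > 0 else np.nan,
                    "distance": res.distance if res.defined else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    slopes: dict[int, dict[str, float]] = {}
    for pos in (1, 2, 3):
        sub = table[(table["position"] == pos) & table["distance"].notna()]
        if len(sub) >= 2 and sub["distance"].nunique() > 1:
            sp = np.polyfit(sub["distance"], sub["P"], 1)[0]
            sq = np.polyfit(sub["distance"], sub["Q"], 1)[0]
        else:
            sp = sq = np.nan
        slopes[pos] = {"transition_slope": float(sp), "transversion_slope": float(sq)}
    return {"table": table, "slopes": slopes}


# ---------------------------------------------------------------------------
# NJ sanity tree
# ---------------------------------------------------------------------------

def supermatrix_nj(matrix: Supermatrix) -> PhyloTree:
    """NJ tree on whole-supermatrix K2P distances (sanity check only)."""
    aln = matrix.alignment
    n = len(matrix.taxa)
    vals = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        res = k2p(aln.seqs[i], aln.seqs[j])
        vals[i, j] = vals[j, i] = res.distance if res.defined else np.nan
    dm = DistanceMatrix(ids=list(matrix.taxa), values=vals)
    return nj_tree(dm)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_for_inference(matrix: Supermatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write relaxed PHYLIP, NEXUS (with charsets), and RAxML partitions.

    Outputs are byte-stable for a given matrix; external ML/BI tools
    (IQ-TREE, PhyloBayes, ...) consume these directly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln = matrix.alignment
    phylip = out / f"supermatrix_{matrix.scheme}.phy"
    with open(phylip, "w") as fh:
        fh.write(f"{len(aln.ids)} {aln.length}\n")
        for tid, seq in zip(aln.ids, aln.seqs):
            fh.write(f"{tid}  {seq}\n")
    nexus = out / f"supermatrix_{matrix.scheme}.nex"
    with open(nexus, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(
            f"  DIMENSIONS NTAX={len(aln.ids)} NCHAR={aln.length};\n"
            "  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n"
        )
        for tid, seq in zip(aln.ids, aln.seqs):
            fh.write(f"    {tid}  {seq}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for gene, (start, end) in matrix.partitions.items():
            fh.write(f"  CHARSET {gene} = {start + 1}-{end};\n")
        fh.write("END;\n")
    parts = out / f"partitions_{matrix.scheme}.txt"
    with open(parts, "w") as fh:
        for gene, (start, end) in matrix.partitions.items():
            fh.write(f"DNA, {gene} = {start + 1}-{end}\n")
    return {"phylip": phylip, "nexus": nexus, "partitions": parts}


def read_relaxed_phylip(path: str | Path) -> MultipleAlignment:
    """Re-import a relaxed PHYLIP file written by ``export_for_inference``."""
    lines = Path(path).read_text().splitlines()
    ntax, nchar = (int(x) for x in lines[0].split())
    ids: list[str] = []
    seqs: list[str] = []
    for line in lines[1: 1 + ntax]:
        name, seq = line.split(None, 1)
        ids.append(name)
        seqs.append(seq.strip())
    if any(len(s) != nchar for s in seqs):
        raise ValueError(f"{path}: sequence lengths do not match header")
    return MultipleAlignment(
        ids=tuple(ids), seqs=tuple(seqs), alphabet="nucleotide"
    )


def monophyly_check(tree: PhyloTree, taxa: Sequence[str]) -> bool:
    return is_monophyletic(tree, taxa)
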