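"""Kimura 2-parameter distances per gene pair.

K2P separates transition (P) and transversion (Q) proportions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Gap handling is pairwise deletion (columns with a gap or N in either
sequence are skipped for that pair only), matching MEGA's default. The
correction leaves the distance undefined — flagged, never silently zeroed
— when 1 - 2P - Q <= 0 or 1 - 2Q <= 0, or when no sites remain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import GAP, progressive_align
from .genbank_io import (
    DEFAULT_CODE,
    GeneticCode,
    MitoGenome,
    PCG_NAMES,
    gene_sequences,
)
from .trees import DistanceMatrix

__all__ = [
    "K2PResult",
    "k2p",
    "per_gene_k2p",
    "summarize_k2p",
    "k2p_distance_matrix",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class K2PResult:
    P: float
    Q: float
    sites_compared: int
    distance: float | None

    @property
    def defined(self) -> bool:
        return self.distance is not None


def is_transition(x: str, y: str) -> bool:
    return x != y and (
        (x in _PURINES and y in _PURINES)
        or (x in _PYRIMIDINES and y in _PYRIMIDINES)
    )


def k2p(a: str, b: str) -> K2PResult:
    """K2P distance between two aligned nucleotide strings."""
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue  # pairwise deletion of gaps and N
        sites += 1
        if x == y:
            continue
        if is_transition(x, y):
            ts += 1
        else:
            tv += 1
    if sites == 0:
        return K2PResult(P=0.0, Q=0.0, sites_compared=0, distance=None)
    P, Q = ts / sites, tv / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(P=P, Q=Q, sites_compared=sites, distance=None)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(P=P, Q=Q, sites_compared=sites, distance=d)


def per_gene_k2p(
    genomes: Sequence[MitoGenome],
    genes: Sequence[str] = PCG_NAMES,
    *,
    code: GeneticCode = DEFAULT_CODE,
) -> pd.DataFrame:
    """K2P for every unordered genome pair within each gene.

    Each gene is extracted in coding sense, codon-aware aligned across the
    genomes that carry it, and compared pairwise. Pairs where a genome
    lacks the gene are emitted with NaN and ``defined=False``.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    ids = [g.id for g in genomes]
    rows: list[dict] = []
    for gene in genes:
        present = {
            g.id: gene_sequences(g, [gene]).get(gene) for g in genomes
        }
        have = {k: v for k, v in present.items() if v}
        aln = None
        if len(have) >= 2:
            aln = progressive_align(have, code=code)
        for ti, tj in combinations(ids, 2):
            if aln is None or ti not in have or tj not in have:
                rows.append(
                    {
                        "gene": gene, "taxon_i": ti, "taxon_j": tj,
                        "P": np.nan, "Q": np.nan, "sites": 0,
                        "distance": np.nan, "defined": False,
                    }
                )
                continue
            res = k2p(aln.get(ti), aln.get(tj))
            rows.append(
                {
                    "gene": gene, "taxon_i": ti, "taxon_j": tj,
                    "P": res.P, "Q": res.Q, "sites": res.sites_compared,
                    "distance": res.distance if res.defined else np.nan,
                    "defined": res.defined,
                }
            )
    return pd.DataFrame(rows)


def summarize_k2p(table: pd.DataFrame) -> dict:
    """Cross-gene summaries of a ``per_gene_k2p`` table.

    Returns overall mean/min/max with gene and pair labels, per-gene
    five-number summaries, and the count of excluded undefined entries.
    """
    defined = table[table["defined"]].copy()
    if defined.empty:
        raise ValueError("no defined distances to summarize")
    imin = defined["distance"].idxmin()
    imax = defined["distance"].idxmax()
    per_gene = (
        defined.groupby("gene")["distance"]
        .agg(["mean", "median", "min", "max",
              lambda s: s.quantile(0.25), lambda s: s.quantile(0.75)])
        .rename(columns={"<lambda_0>": "q1", "<lambda_1>": "q3"})
        .reset_index()
    )
    row_min, row_max = table.loc[imin], table.loc[imax]
    return {
        "mean": float(defined["distance"].mean()),
        "min": {
            "value": float(row_min["distance"]),
            "gene": row_min["gene"],
            "pair": (row_min["taxon_i"], row_min["taxon_j"]),
        },
        "max": {
            "value": float(row_max["distance"]),
            "gene": row_max["gene"],
            "pair": (row_max["taxon_i"], row_max["taxon_j"]),
        },
        "per_gene": per_gene,
        "n_undefined": int((~table["defined"]).sum()),
    }


def k2p_distance_matrix(seqs: dict[str, str]) -> DistanceMatrix:
    """Square K2P matrix over named aligned sequences (NaN = undefined)."""
    ids = list(seqs)
    n = len(ids)
    vals = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        res = k2p(seqs[ids[i]], seqs[ids[j]])
        vals[i, j] = vals[j, i] = res.distance if res.defined else np.nan
    return DistanceMatrix(ids=ids, values=vals)


def write_phylip_matrix(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP-style distance matrix for interchange."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, name in enumerate(dm.ids):
            row = " ".join(
                "NA" if np.isnan(v) else f"{v:.6f}" for v in dm.values[i]
            )
            fh.write(f"{name:<12s} {row}\n")
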