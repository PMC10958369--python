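"""Nei–Gojobori (1986) Ka/Ks estimation and the purifying-selection screen.

The unweighted-pathway NG86 method, i.e. the computation DnaSP performs:

* potential sites: at each codon position the fraction of the three
  possible single-base changes that are synonymous under the active
  genetic code contributes to S, the remainder to N (changes creating a
  stop codon count as nonsynonymous); site counts are averaged over the
  two sequences, so S + N = 3 x compared codons exactly;
* observed differences: codons differing at several positions average
  their synonymous/nonsynonymous split over all minimal mutational
  pathways, excluding pathways that pass through a stop codon — if every
  pathway does, the codon pair is skipped and tallied in a diagnostics
  field;
* proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
  d = -3/4 * ln(1 - 4p/3), undefined for p >= 3/4.

Ka/Ks < 1 indicates purifying selection. Codons containing a gap or N in
either sequence are deleted pairwise, consistent with the distance module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import progressive_align
from .genbank_io import (
    DEFAULT_CODE,
    GeneticCode,
    MitoGenome,
    PCG_NAMES,
    gene_sequences,
)

__all__ = ["KaKsResult", "ng86", "selection_screen"]

_BASES = "ACGT"


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    Ks: float | None
    Ka: float | None
    ratio: float | None
    codons_compared: int
    codons_skipped_stop_paths: int = 0

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@lru_cache(maxsize=None)
def _syn_sites(codon: str, table_id: int) -> float:
    """Synonymous potential sites of one codon (0..3)."""
    code = GeneticCode.from_table(table_id)
    aa = code.codon_to_aa[codon]
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            # changes to stop codons count as nonsynonymous
            if not code.is_stop(mut) and code.codon_to_aa[mut] == aa:
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str, table_id: int) -> tuple[float, float, int]:
    """Average (Sd, Nd) over all minimal mutational pathways c1 -> c2.

    Pathways crossing a stop codon are excluded. Returns (Sd, Nd,
    n_valid_pathways); n_valid_pathways == 0 means every route is blocked.
    """
    code = GeneticCode.from_table(table_id)
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0, 1
    syn_tot = nsyn_tot = 0.0
    n_valid = 0
    for order in permutations(diff_pos):
        cur = c1
        syn = nsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            # endpoints are sense codons (stop codons are filtered out
            # before pathway counting), so a stop here is an intermediate
            if code.is_stop(nxt):
                blocked = True
                break
            if code.codon_to_aa[cur] == code.codon_to_aa[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if not blocked:
            syn_tot += syn
            nsyn_tot += nsyn
            n_valid += 1
    if n_valid == 0:
        return 0.0, 0.0, 0
    return syn_tot / n_valid, nsyn_tot / n_valid, n_valid


def _iter_codon_pairs(a: str, b: str):
    for i in range(0, len(a), 3):
        yield a[i: i + 3], b[i: i + 3]


def ng86(
    a: str,
    b: str,
    code: GeneticCode = DEFAULT_CODE,
) -> KaKsResult:
    """NG86 Ka/Ks between two aligned, in-frame codon strings.

    Codons with a gap or N in either sequence are skipped (pairwise codon
    deletion), as are stop codons and codon pairs whose every mutational
    pathway crosses a stop (tallied in ``codons_skipped_stop_paths``).
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError(f"aligned length {len(a)} is not codon-divisible")
    a, b = a.upper(), b.upper()
    S = N = Sd = Nd = 0.0
    n_codons = 0
    n_blocked = 0
    for ca, cb in _iter_codon_pairs(a, b):
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        sd, nd, n_valid = _pathway_counts(ca, cb, code.table_id)
        if n_valid == 0:
            n_blocked += 1
            continue
        n_codons += 1
        sa = _syn_sites(ca, code.table_id)
        sb = _syn_sites(cb, code.table_id)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    Ks = _jc_correct(pS) if pS is not None else None
    Ka = _jc_correct(pN) if pN is not None else None
    # Ka = 0 pins the ratio at 0 even when Ks saturates out of the JC
    # domain; a zero or undefined denominator otherwise leaves it undefined
    if Ka == 0.0 and Ks != 0.0:
        ratio = 0.0
    elif Ks is None or Ka is None or Ks == 0.0:
        ratio = None
    else:
        ratio = Ka / Ks
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio,
        codons_compared=n_codons, codons_skipped_stop_paths=n_blocked,
    )


def selection_screen(
    genomes: Sequence[MitoGenome],
    genes: Sequence[str] = PCG_NAMES,
    *,
    code: GeneticCode = DEFAULT_CODE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene Ka/Ks over all genome pairs, with classification.

    Returns ``(pairwise, per_gene)``: the long table of pairwise NG86
    results and a per-gene summary with mean Ka, mean Ks, mean of defined
    ratios, and classification ``purifying`` iff mean ratio < 1, else
    ``neutral/positive``.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    ids = [g.id for g in genomes]
    rows: list[dict] = []
    for gene in genes:
        have = {
            g.id: s for g in genomes
            for s in [gene_sequences(g, [gene]).get(gene)] if s
        }
        aln = progressive_align(have, code=code) if len(have) >= 2 else None
        for ti, tj in combinations(ids, 2):
            if aln is None or ti not in have or tj not in have:
                rows.append({"gene": gene, "taxon_i": ti, "taxon_j": tj,
                             "S": np.nan, "N": np.nan, "Sd": np.nan,
                             "Nd": np.nan, "Ka": np.nan, "Ks": np.nan,
                             "ratio": np.nan, "skipped_stop_paths": 0})
                continue
            res = ng86(aln.get(ti), aln.get(tj), code)
            rows.append(
                {
                    "gene": gene, "taxon_i": ti, "taxon_j": tj,
                    "S": res.S, "N": res.N, "Sd": res.Sd, "Nd": res.Nd,
                    "Ka": res.Ka if res.Ka is not None else np.nan,
                    "Ks": res.Ks if res.Ks is not None else np.nan,
                    "ratio": res.ratio if res.ratio is not None else np.nan,
                    "skipped_stop_paths": res.codons_skipped_stop_paths,
                }
            )
    pairwise = pd.DataFrame(rows)
    summaries = []
    for gene, grp in pairwise.groupby("gene", sort=False):
        ratios = grp["ratio"].dropna()
        mean_ratio = float(ratios.mean()) if len(ratios) else np.nan
        summaries.append(
            {
                "gene": gene,
                "mean_Ka": float(grp["Ka"].mean()),
                "mean_Ks": float(grp["Ks"].mean()),
                "mean_ratio": mean_ratio,
                "n_defined_ratios": int(len(ratios)),
                "classification": (
                    "purifying" if mean_ratio < 1.0 else "neutral/positive"
                ) if not np.isnan(mean_ratio) else "undefined",
            }
        )
    return pairwise, pd.DataFrame(summaries)
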