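"""Base composition and AT/GC skew statistics.

Skews measure the strand asymmetry of base usage:

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

Mitogenomes replicate asymmetrically, so the two strands accumulate
different biases; comparing skews per strand group and per codon position
is a standard descriptive layer of mitogenome papers. All statistics here
exclude N per site and flag (rather than zero) undefined skews.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genbank_io import DEFAULT_CODE, GeneticCode, MitoGenome, feature_sequence

__all__ = [
    "CompositionStats",
    "SkewStats",
    "composition",
    "skew",
    "positional_skew",
    "strand_pcg_sequences",
]

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class CompositionStats:
    counts: dict[str, int]          # A, C, G, T, N
    fractions: dict[str, float]     # over non-N sites; empty when all-N
    at_content: float | None
    gc_content: float | None

    @property
    def defined(self) -> bool:
        return self.at_content is not None


@dataclass(frozen=True)
class SkewStats:
    at_skew: float | None
    gc_skew: float | None

    @property
    def at_defined(self) -> bool:
        return self.at_skew is not None

    @property
    def gc_defined(self) -> bool:
        return self.gc_skew is not None


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"sequence contains non-{{A,C,G,T,N}} characters: {sorted(bad)}")


def composition(seq: str) -> CompositionStats:
    """Base counts and fractions; N excluded from all denominators."""
    seq = seq.upper()
    _check_alphabet(seq)
    c = Counter(seq)
    counts = {b: c.get(b, 0) for b in "ACGTN"}
    informative = sum(counts[b] for b in "ACGT")
    if informative == 0:
        return CompositionStats(counts, {}, None, None)
    fractions = {b: counts[b] / informative for b in "ACGT"}
    return CompositionStats(
        counts,
        fractions,
        at_content=fractions["A"] + fractions["T"],
        gc_content=fractions["G"] + fractions["C"],
    )


def skew(seq: str) -> SkewStats:
    """AT and GC skew; undefined (None) on a zero denominator."""
    stats = composition(seq)
    a, t = stats.counts["A"], stats.counts["T"]
    g, cc = stats.counts["G"], stats.counts["C"]
    at = (a - t) / (a + t) if (a + t) > 0 else None
    gc = (g - cc) / (g + cc) if (g + cc) > 0 else None
    return SkewStats(at_skew=at, gc_skew=gc)


def strand_pcg_sequences(
    genome: MitoGenome,
    *,
    code: GeneticCode = DEFAULT_CODE,
    exclude_stops: bool = True,
) -> dict[str, str]:
    """Concatenated coding-sense PCG sequence per strand group ('J'/'N').

    Trailing partial codons (truncated stops completed by polyadenylation)
    are trimmed; complete terminal stop codons are dropped by default so
    codon-position pools are not contaminated by termination signals.
    """
    pools: dict[str, list[str]] = {"J": [], "N": []}
    for feat in genome.pcgs():
        seq = feature_sequence(genome, feat)
        seq = seq[: len(seq) - len(seq) % 3]
        if exclude_stops and len(seq) >= 3 and code.is_stop(seq[-3:]):
            seq = seq[:-3]
        pools[feat.strand].append(seq)
    return {s: "".join(parts) for s, parts in pools.items() if parts}


def positional_skew(
    genomes: Iterable[MitoGenome],
    *,
    code: GeneticCode = DEFAULT_CODE,
    exclude_stops: bool = True,
) -> pd.DataFrame:
    """Skew and composition by (species, strand group, codon position).

    Per strand group the coding-sense PCG sequences are concatenated and
    split by codon position (1, 2, 3); position ``all`` pools every site of
    the strand group. Strand groups with no PCGs are omitted with a warning.
    """
    import warnings

    rows: list[dict] = []
    for genome in genomes:
        pools = strand_pcg_sequences(genome, code=code, exclude_stops=exclude_stops)
        for strand in ("J", "N"):
            if strand not in pools:
                warnings.warn(
                    f"{genome.id}: no PCGs on strand {strand}; row omitted",
                    stacklevel=2,
                )
                continue
            pooled = pools[strand]
            subsets: Sequence[tuple[str, str]] = [
                ("1", pooled[0::3]),
                ("2", pooled[1::3]),
                ("3", pooled[2::3]),
                ("all", pooled),
            ]
            for pos, subseq in subsets:
                comp = composition(subseq)
                sk = skew(subseq)
                rows.append(
                    {
                        "species": genome.source_taxon or genome.id,
                        "accession": genome.id,
                        "strand": strand,
                        "position": pos,
                        "sites": sum(comp.counts[b] for b in "ACGT"),
                        "frac_A": comp.fractions.get("A"),
                        "frac_C": comp.fractions.get("C"),
                        "frac_G": comp.fractions.get("G"),
                        "frac_T": comp.fractions.get("T"),
                        "at_content": comp.at_content,
                        "gc_content": comp.gc_content,
                        "at_skew": sk.at_skew,
                        "gc_skew": sk.gc_skew,
                    }
                )
    return pd.DataFrame(rows)
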