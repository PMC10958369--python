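"""Codon usage, RSCU, and amino-acid frequencies.

Relative synonymous codon usage (RSCU) for a codon c in a synonymous
family F is

    RSCU(c) = count(c) * |F| / sum_{c' in F} count(c')

so the mean RSCU within any family with nonzero usage is exactly 1, and a
value above 1 marks a codon used more often than expected under equal
usage. Families are defined by the active genetic code — under the
invertebrate mitochondrial code (table 5) Ser has 8 codons (AGN joins
UCN), Leu 6, and only TAA/TAG are stops.

Stop codons and incomplete terminal codons are excluded by default: insect
mitochondrial PCGs frequently end in a truncated stop (T or TA) completed
by polyadenylation, and termination signals are not subject to synonymous
choice.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .genbank_io import DEFAULT_CODE, GeneticCode, MitoGenome, feature_sequence

__all__ = [
    "CodonUsageTable",
    "RscuFraction",
    "translate",
    "count_codons",
    "codon_counts",
    "rscu_fraction_above",
    "aa_frequencies",
]


def translate(codon_seq: str, code: GeneticCode = DEFAULT_CODE) -> str:
    """Translate a codon-divisible nucleotide string.

    Codons containing N translate to 'X'. An internal stop raises a
    warning naming the position (annotation problems must surface), and is
    rendered '*'.
    """
    codon_seq = codon_seq.upper()
    if len(codon_seq) % 3:
        raise ValueError(
            f"sequence length {len(codon_seq)} is not divisible by 3"
        )
    aas: list[str] = []
    n_codons = len(codon_seq) // 3
    for i in range(n_codons):
        codon = codon_seq[3 * i: 3 * i + 3]
        aa = code.translate_codon(codon)
        if aa == "*" and i < n_codons - 1:
            warnings.warn(
                f"internal stop codon {codon} at codon {i + 1}", stacklevel=2
            )
        aas.append(aa)
    return "".join(aas)


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts with RSCU and per-amino-acid totals."""

    code: GeneticCode
    counts: Mapping[str, int]          # sense codons only
    rscu: Mapping[str, float | None]   # None when the family is unused
    aa_counts: Mapping[str, int]
    n_codons: int                      # total complete sense codons counted
    n_skipped_ambiguous: int = 0
    n_stop_codons: int = 0

    def aa_frequencies(self) -> dict[str, float]:
        total = sum(self.aa_counts.values())
        if total == 0:
            return {}
        return {aa: n / total for aa, n in self.aa_counts.items()}

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": codon,
                "aa": self.code.translate_codon(codon),
                "count": self.counts[codon],
                "rscu": self.rscu[codon],
            }
            for codon in sorted(self.counts)
        ]
        return pd.DataFrame(rows)


def _trim_coding(seq: str, code: GeneticCode, exclude_stops: bool) -> str:
    seq = seq[: len(seq) - len(seq) % 3]
    if exclude_stops and len(seq) >= 3 and code.is_stop(seq[-3:]):
        seq = seq[:-3]
    return seq


def count_codons(
    seqs: Iterable[str],
    code: GeneticCode = DEFAULT_CODE,
    *,
    exclude_stops: bool = True,
) -> CodonUsageTable:
    """Build a codon usage table from coding-sense sequences.

    Trailing partial codons are trimmed; complete terminal stop codons are
    dropped when ``exclude_stops`` (the default). Codons containing N are
    skipped and tallied; internal stops are counted separately and kept
    out of RSCU.
    """
    families = code.synonymous_families()
    counter: Counter[str] = Counter()
    skipped = 0
    stops = 0
    for seq in seqs:
        seq = _trim_coding(seq.upper(), code, exclude_stops)
        for i in range(0, len(seq), 3):
            codon = seq[i: i + 3]
            if "N" in codon:
                skipped += 1
                continue
            if code.is_stop(codon):
                stops += 1
                continue
            counter[codon] += 1
    counts = {
        codon: counter.get(codon, 0)
        for fam in families.values()
        for codon in fam
    }
    rscu: dict[str, float | None] = {}
    aa_counts: dict[str, int] = {}
    for aa, fam in families.items():
        total = sum(counts[c] for c in fam)
        aa_counts[aa] = total
        for c in fam:
            rscu[c] = counts[c] * len(fam) / total if total > 0 else None
    return CodonUsageTable(
        code=code,
        counts=counts,
        rscu=rscu,
        aa_counts=aa_counts,
        n_codons=sum(counts.values()),
        n_skipped_ambiguous=skipped,
        n_stop_codons=stops,
    )


def codon_counts(
    genome: MitoGenome,
    code: GeneticCode = DEFAULT_CODE,
    *,
    exclude_stops: bool = True,
) -> CodonUsageTable:
    """Codon usage pooled over all PCGs of one genome, in coding sense."""
    pcgs = genome.pcgs()
    if not pcgs:
        raise ValueError(f"{genome.id}: genome has no PCGs")
    seqs = [feature_sequence(genome, f) for f in pcgs]
    return count_codons(seqs, code, exclude_stops=exclude_stops)


class RscuFraction(NamedTuple):
    fraction: float
    numerator: int
    denominator: int


def rscu_fraction_above(
    table: CodonUsageTable, threshold: float = 1.0
) -> RscuFraction:
    """Proportion of defined RSCU values strictly above ``threshold``.

    Numerator and denominator are reported explicitly because published
    percentages for this statistic depend on how many codons the authors'
    tool put in the denominator (62 sense codons, 60 excluding
    single-codon families, ...).
    """
    defined = [v for v in table.rscu.values() if v is not None]
    numer = sum(1 for v in defined if v > threshold)
    denom = len(defined)
    return RscuFraction(numer / denom if denom else 0.0, numer, denom)


def aa_frequencies(
    genomes: Iterable[MitoGenome],
    code: GeneticCode = DEFAULT_CODE,
) -> pd.DataFrame:
    """Per-genome amino-acid frequency table over translated PCG codons."""
    rows = []
    for genome in genomes:
        table = codon_counts(genome, code)
        freqs = table.aa_frequencies()
        row = {"accession": genome.id, "species": genome.source_taxon or genome.id}
        row.update({aa: freqs.get(aa, 0.0) for aa in sorted(table.aa_counts)})
        rows.append(row)
    return pd.DataFrame(rows)
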