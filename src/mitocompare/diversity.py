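"""Sliding-window nucleotide diversity and gene-order (synteny) accounting.

Nucleotide diversity (Pi) in a window is the pooled proportion of
differing sites over all sequence pairs,

    Pi = sum_pairs(differences) / sum_pairs(compared sites)

with gap/N columns deleted pairwise. Pooling (rather than averaging the
per-pair ratios) makes the weighted aggregation identity exact: summing
``sites * Pi`` over non-overlapping windows and dividing by total sites
recovers whole-alignment Pi. On gap-free data the two estimators
coincide.

Synteny is summarized as the circular, strand-aware gene order plus a
junction table (overlap / spacer / abutting, with lengths), and compared
between genomes by breakpoint count over strand-aware adjacencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import MultipleAlignment
from .genbank_io import GeneFeature, MitoGenome

__all__ = [
    "WindowDiversity",
    "SyntenyRecord",
    "sliding_pi",
    "whole_alignment_pi",
    "gene_order",
    "compare_orders",
    "junction_table",
]


@dataclass(frozen=True)
class WindowDiversity:
    start: int          # alignment coordinate
    length: int         # actual window span (final window may be short)
    step: int
    pi: float | None    # None when no site could be compared
    sites: int          # compared sites summed over pairs
    partial: bool = False

    @property
    def midpoint(self) -> float:
        return self.start + self.length / 2.0


_VALID = frozenset(b"ACGT")


def _pair_masks(aln: MultipleAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair boolean arrays: (valid columns, differing columns)."""
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in aln.seqs]
    ok = [np.isin(arr, [b"A", b"C", b"G", b"T"]) for arr in arrs]
    valid_rows = []
    diff_rows = []
    for i, j in combinations(range(len(arrs)), 2):
        valid = ok[i] & ok[j]
        diff = valid & (arrs[i] != arrs[j])
        valid_rows.append(valid)
        diff_rows.append(diff)
    return np.array(valid_rows), np.array(diff_rows)


def sliding_pi(
    aln: MultipleAlignment, window: int, step: int
) -> list[WindowDiversity]:
    """Pi in sliding windows over an alignment (DnaSP-style analysis)."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if len(aln.ids) < 2:
        raise ValueError("need at least two sequences")
    L = aln.length
    if window > L:
        raise ValueError(f"window {window} exceeds alignment length {L}")
    valid, diff = _pair_masks(aln)
    cum_valid = np.concatenate(
        [np.zeros((valid.shape[0], 1), dtype=int), np.cumsum(valid, axis=1)], axis=1
    )
    cum_diff = np.concatenate(
        [np.zeros((diff.shape[0], 1), dtype=int), np.cumsum(diff, axis=1)], axis=1
    )
    out: list[WindowDiversity] = []
    for start in range(0, L, step):
        end = min(start + window, L)
        n_valid = int((cum_valid[:, end] - cum_valid[:, start]).sum())
        n_diff = int((cum_diff[:, end] - cum_diff[:, start]).sum())
        out.append(
            WindowDiversity(
                start=start,
                length=end - start,
                step=step,
                pi=(n_diff / n_valid) if n_valid else None,
                sites=n_valid,
                partial=end - start < window,
            )
        )
        if end == L:
            break
    return out


def whole_alignment_pi(aln: MultipleAlignment) -> float | None:
    """Pooled Pi over the full alignment."""
    [w] = sliding_pi(aln, window=aln.length, step=aln.length)
    return w.pi


def windows_to_frame(windows: Sequence[WindowDiversity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start": w.start, "midpoint": w.midpoint, "length": w.length,
                "pi": w.pi, "sites": w.sites, "partial": w.partial,
            }
            for w in windows
        ]
    )


# ---------------------------------------------------------------------------
# Synteny
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntenyRecord:
    """Gene order plus junction relations of one genome."""

    genome_id: str
    order: tuple[tuple[str, str], ...]          # (gene, strand) by fwd start
    junctions: tuple[tuple[str, str, str, int], ...]
    # (upstream, downstream, relation in {overlap, spacer, abutting}, bp)

    def adjacency_set(self, circular: bool = True) -> frozenset:
        """Strand-aware adjacency set; an adjacency equals its
        reverse-complement reading."""
        adjs = []
        order = self.order
        n = len(order)
        last = n if circular else n - 1
        for i in range(last):
            a = order[i]
            b = order[(i + 1) % n]
            flip = {"J": "N", "N": "J"}
            canonical = min(
                (a, b), ((b[0], flip[b[1]]), (a[0], flip[a[1]]))
            )
            adjs.append(canonical)
        return frozenset(adjs)


def _fwd_span(feat: GeneFeature, L: int) -> tuple[int, int]:
    """Forward-strand [start, end) with end possibly beyond L for wrap."""
    if feat.wraps_origin:
        return feat.start, feat.end + L
    return feat.start, feat.end


def gene_order(genome: MitoGenome) -> SyntenyRecord:
    """Ordered (gene, strand) list and junction table of one genome."""
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    if not feats:
        raise ValueError(f"{genome.id}: genome has no features")
    order = tuple((f.name, f.strand) for f in feats)
    junctions = tuple(_junctions(genome, feats))
    return SyntenyRecord(genome_id=genome.id, order=order, junctions=junctions)


def _junctions(genome: MitoGenome, feats: list[GeneFeature]):
    L = genome.length
    n = len(feats)
    last = n if genome.circular else n - 1
    for i in range(last):
        a, b = feats[i], feats[(i + 1) % n]
        _, a_end = _fwd_span(a, L)
        b_start, _ = _fwd_span(b, L)
        if i == n - 1:  # circular closure: next start is one full turn on
            b_start += L
        gap = b_start - a_end
        if gap > 0:
            yield (a.name, b.name, "spacer", gap)
        elif gap < 0:
            yield (a.name, b.name, "overlap", -gap)
        else:
            yield (a.name, b.name, "abutting", 0)


def junction_table(genome: MitoGenome) -> pd.DataFrame:
    """Overlaps/spacers between consecutive features, as a DataFrame."""
    rec = gene_order(genome)
    return pd.DataFrame(
        rec.junctions, columns=["upstream", "downstream", "relation", "bp"]
    )


def compare_orders(a: SyntenyRecord, b: SyntenyRecord) -> dict:
    """Breakpoint comparison of two (circular) gene orders.

    ``breakpoint_count`` is the number of strand-aware adjacencies present
    in ``a`` but absent from ``b``; symmetric whenever both genomes carry
    the same gene set.
    """
    adj_a = a.adjacency_set()
    adj_b = b.adjacency_set()
    breakpoints = len(adj_a - adj_b)
    return {
        "identical": adj_a == adj_b,
        "breakpoint_count": breakpoints,
    }
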