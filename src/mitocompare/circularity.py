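"""Assembly-completeness (circularity) verification.

De novo assemblers commonly emit a circular mitochondrial molecule as a
linear contig carrying an artefactual duplication of its start at its
end. The procedure here mirrors the trim / join / rotate / re-map
strategy used to finish such assemblies:

1. detect the terminal repeat (longest prefix matching a suffix within a
   mismatch tolerance, default 1% — assembler end artifacts are
   near-exact);
2. trim the duplicated suffix and rotate the circle so the former
   junction sits mid-sequence (deterministic rotation: an anchor gene
   when given, else half the length — a reproducible stand-in for
   splitting "randomly");
3. place reads by exact k-mer seeding with ungapped extension and count
   those spanning the former junction on both sides.

This is deliberately a desk-scale verifier, not a read mapper: the goal
is junction support, not alignment fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "CircularizationReport",
    "detect_terminal_repeat",
    "rotate_and_join",
    "junction_support",
    "read_fastq",
]


@dataclass(frozen=True)
class CircularizationReport:
    input_length: int
    terminal_repeat: int
    trimmed_length: int
    rotation_offset: int
    junction_position: int
    spanning_reads: int
    placed_reads: int
    total_reads: int
    mean_coverage: float
    verdict: str  # circular_supported | circular_unsupported | linear


def detect_terminal_repeat(
    contig: str, min_repeat: int = 50, max_mismatch_rate: float = 0.01
) -> int:
    """Length of the longest suffix repeating the contig's prefix.

    Scans candidate lengths from ``len(contig) // 2`` down to
    ``min_repeat``; a candidate matches when its per-base mismatch rate is
    at most ``max_mismatch_rate``. Returns 0 when nothing qualifies.
    """
    contig = contig.upper()
    L = len(contig)
    if L <= 2 * min_repeat:
        raise ValueError(
            f"contig length {L} too short for min_repeat {min_repeat}"
        )
    for k in range(L // 2, min_repeat - 1, -1):
        prefix = contig[:k]
        suffix = contig[L - k:]
        budget = int(max_mismatch_rate * k)
        mismatches = 0
        for x, y in zip(prefix, suffix):
            if x != y:
                mismatches += 1
                if mismatches > budget:
                    break
        else:
            return k
    return 0


def rotate_and_join(
    contig: str,
    repeat_len: int,
    anchor_offset: int | None = None,
) -> tuple[str, int]:
    """Trim the terminal repeat and rotate the resulting circle.

    ``anchor_offset`` is the position (on the trimmed circle) that should
    become the new origin — typically the start of an anchor gene such as
    trnI. By default the circle is rotated by half its length, which puts
    the former junction mid-sequence. Returns ``(sequence, offset)`` where
    ``offset`` is the rotation applied; the former junction (old position
    0) now sits at ``(L - offset) % L``.
    """
    contig = contig.upper()
    if repeat_len < 0 or repeat_len > len(contig) // 2:
        raise ValueError(f"invalid repeat length {repeat_len}")
    trimmed = contig[: len(contig) - repeat_len] if repeat_len else contig
    L = len(trimmed)
    offset = (L // 2) if anchor_offset is None else anchor_offset % L
    rotated = trimmed[offset:] + trimmed[:offset]
    return rotated, offset


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """FASTQ -> list of (read id, sequence)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def _place_read(
    read: str,
    index: dict[str, list[int]],
    doubled: str,
    k: int,
    L: int,
    max_mismatch_rate: float = 0.05,
) -> int | None:
    """Best start position of ``read`` on the circle, or None.

    Seeds with the read's first k-mer and extends without gaps over the
    doubled sequence; among seed hits the leftmost placement within the
    mismatch budget wins.
    """
    if len(read) < k:
        return None
    seed = read[:k]
    best = None
    budget = int(max_mismatch_rate * len(read))
    for pos in index.get(seed, ()):
        if pos >= L:  # same placement as pos - L
            continue
        window = doubled[pos: pos + len(read)]
        if len(window) < len(read):
            continue
        mism = sum(1 for x, y in zip(read, window) if x != y)
        if mism <= budget and (best is None or pos < best):
            best = pos
    return best


def junction_support(
    reads: Iterable[tuple[str, str]] | str | Path,
    circle: str,
    *,
    junction: int | None = None,
    k: int = 31,
    flank: int = 20,
    min_span_reads: int = 5,
    assume_circular_placement: bool = True,
) -> CircularizationReport:
    """Count reads whose placement spans a junction of a circular sequence.

    ``junction`` defaults to position 0 (i.e. verify the join at the
    sequence start, appropriate right after ``rotate_and_join`` rotated
    the former junction elsewhere — pass its reported position to test
    that one instead). Verdict is ``circular_supported`` when at least
    ``min_span_reads`` reads cover the junction by ``flank`` bp on both
    sides, ``circular_unsupported`` when reads place but none span, and
    ``linear`` when nothing places at all.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    reads = list(reads)
    circle = circle.upper()
    L = len(circle)
    junction = 0 if junction is None else junction % L
    doubled = circle + circle  # wraps are plain substrings of the doubling
    index: dict[str, list[int]] = {}
    for i in range(len(doubled) - k + 1):
        index.setdefault(doubled[i: i + k], []).append(i)

    placed = 0
    spanning = 0
    covered = 0
    for _, seq in reads:
        pos = _place_read(seq, index, doubled, k, L)
        if pos is None:
            continue
        placed += 1
        covered += len(seq)
        end = pos + len(seq)  # may exceed L: the read wraps the origin
        if not assume_circular_placement and end > L:
            continue
        # does [pos, end) contain junction with >= flank on both sides?
        for j in (junction, junction + L):
            if pos + flank <= j <= end - flank:
                spanning += 1
                break
    mean_cov = covered / L if L else 0.0
    if placed == 0:
        import warnings

        warnings.warn("no read placed on the circle; verdict linear", stacklevel=2)
        verdict = "linear"
    elif spanning >= min_span_reads:
        verdict = "circular_supported"
    else:
        verdict = "circular_unsupported"
    return CircularizationReport(
        input_length=L,
        terminal_repeat=0,
        trimmed_length=L,
        rotation_offset=0,
        junction_position=junction,
        spanning_reads=spanning,
        placed_reads=placed,
        total_reads=len(reads),
        mean_coverage=mean_cov,
        verdict=verdict,
    )


def circularize(
    contig: str,
    reads: Iterable[tuple[str, str]] | str | Path | None = None,
    *,
    min_repeat: int = 50,
    max_mismatch_rate: float = 0.01,
    anchor_offset: int | None = None,
    k: int = 31,
    flank: int = 20,
    min_span_reads: int = 5,
) -> tuple[str, CircularizationReport]:
    """Full trim-join-rotate-verify pass over one contig.

    Returns the circularized (trimmed, rotated) sequence and a report.
    Without reads the junction-support fields stay at zero and the verdict
    reflects only whether a terminal repeat was found.
    """
    contig = contig.upper()
    repeat = detect_terminal_repeat(contig, min_repeat, max_mismatch_rate)
    rotated, offset = rotate_and_join(contig, repeat, anchor_offset)
    L = len(rotated)
    junction = (L - offset) % L
    if reads is None:
        return rotated, CircularizationReport(
            input_length=len(contig),
            terminal_repeat=repeat,
            trimmed_length=L,
            rotation_offset=offset,
            junction_position=junction,
            spanning_reads=0,
            placed_reads=0,
            total_reads=0,
            mean_coverage=0.0,
            verdict="circular_unsupported" if repeat else "linear",
        )
    rep = junction_support(
        reads, rotated, junction=junction, k=k, flank=flank,
        min_span_reads=min_span_reads,
    )
    return rotated, CircularizationReport(
        input_length=len(contig),
        terminal_repeat=repeat,
        trimmed_length=L,
        rotation_offset=offset,
        junction_position=junction,
        spanning_reads=rep.spanning_reads,
        placed_reads=rep.placed_reads,
        total_reads=rep.total_reads,
        mean_coverage=rep.mean_coverage,
        verdict=rep.verdict,
    )
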