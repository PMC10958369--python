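"""Codon-aware alignment of orthologous protein-coding genes.

Genes are aligned at the protein level (global Needleman–Wunsch with
affine gaps, BLOSUM62 by default) and back-translated, which keeps the
nucleotide alignment in frame — a requirement for per-gene K2P distances,
Nei–Gojobori counting and codon-position supermatrices. Multiple
alignment is progressive: protein p-distances -> NJ guide tree ->
profile–profile merges in guide-tree order. There is no iterative
refinement; mitochondrial PCGs across congeners are nearly indel-free and
the simple scheme is deterministic.

Determinism rules: traceback prefers match/mismatch over a gap in the
first profile over a gap in the second; guide-tree ties resolve by input
order.
"""

from __future__ import annotations

import numpy as np

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Align import substitution_matrices

from .codons import translate
from .genbank_io import DEFAULT_CODE, GeneticCode
from .trees import DistanceMatrix, nj_tree

__all__ = [
    "PairwiseAlignment",
    "MultipleAlignment",
    "align_protein_pair",
    "backtranslate",
    "progressive_align",
]

_ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_X_INDEX = _AA_INDEX["X"]
GAP = "-"

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


def _blosum62() -> np.ndarray:
    raw = substitution_matrices.load("BLOSUM62")
    n = len(_ALPHABET)
    S = np.zeros((n, n))
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            S[i, j] = raw[a][b]
    return S


_BLOSUM62 = _blosum62()


@dataclass(frozen=True)
class PairwiseAlignment:
    a: str
    b: str
    score: float
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned sequences differ in length")
        for x, y in zip(self.a, self.b):
            if x == GAP and y == GAP:
                raise ValueError("all-gap column in pairwise alignment")


@dataclass(frozen=True)
class MultipleAlignment:
    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    alphabet: str = "codon"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids/seqs length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("aligned sequences differ in length")
        if self.alphabet == "codon" and self.seqs and len(self.seqs[0]) % 3:
            raise ValueError("codon alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def degapped(self, i: int) -> str:
        return self.seqs[i].replace(GAP, "")

    def get(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def pairs(self):
        from itertools import combinations

        return combinations(range(len(self.ids)), 2)


# ---------------------------------------------------------------------------
# Profiles and the DP engine
# ---------------------------------------------------------------------------

class _Profile:
    """A gapped block of sequences as a per-column frequency matrix."""

    __slots__ = ("ids", "rows", "freqs")

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        self.ids = list(ids)
        self.rows = list(rows)
        n = len(rows)
        length = len(rows[0]) if rows else 0
        F = np.zeros((length, len(_ALPHABET)))
        for row in rows:
            for pos, ch in enumerate(row):
                if ch == GAP:
                    continue
                F[pos, _AA_INDEX.get(ch, _X_INDEX)] += 1.0
        self.freqs = F / max(n, 1)

    def __len__(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def _nw_profiles(
    pa: _Profile,
    pb: _Profile,
    matrix: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[tuple[int, int]], float]:
    """Global affine-gap DP between two profiles.

    Returns the aligned column path as (ia, ib) pairs (-1 marks a gap) and
    the optimum score. A gap of length g costs open + extend*(g-1).
    """
    na, nb = len(pa), len(pb)
    if na == 0 or nb == 0:
        raise ValueError("cannot align an empty profile")
    smat = (pa.freqs @ matrix) @ pb.freqs.T  # (na, nb) column-pair scores

    NEG = -1e30
    go, ge = gap_open, gap_extend
    M = np.full((na + 1, nb + 1), NEG)
    GA = np.full((na + 1, nb + 1), NEG)  # gap in B (consumes A)
    GB = np.full((na + 1, nb + 1), NEG)  # gap in A (consumes B)
    M[0, 0] = 0.0
    j = np.arange(1, nb + 1)
    GB[0, 1:] = -(go + ge * (j - 1))
    i = np.arange(1, na + 1)
    GA[1:, 0] = -(go + ge * (i - 1))

    for r in range(1, na + 1):
        prev_best = np.maximum(np.maximum(M[r - 1], GA[r - 1]), GB[r - 1])
        M[r, 1:] = smat[r - 1] + prev_best[:-1]
        GA[r, 1:] = np.maximum(
            np.maximum(M[r - 1, 1:], GB[r - 1, 1:]) - go, GA[r - 1, 1:] - ge
        )
        # GB within this row: unrolled running max of (base[k] + ge*k)
        base = np.maximum(M[r, :-1], GA[r, :-1])
        track = np.maximum.accumulate(base + ge * np.arange(nb))
        GB[r, 1:] = track - go - ge * np.arange(1, nb + 1) + ge

    # traceback; preference: match > gap-in-b(GA, consumes A) > gap-in-a(GB)
    def pick(vals: Sequence[tuple[str, float]]) -> str:
        best = max(v for _, v in vals)
        for name, v in vals:
            if v >= best - 1e-9:
                return name
        return vals[0][0]

    ri, rj = na, nb
    state = pick([("M", M[ri, rj]), ("GA", GA[ri, rj]), ("GB", GB[ri, rj])])
    score = max(M[ri, rj], GA[ri, rj], GB[ri, rj])
    path: list[tuple[int, int]] = []
    while ri > 0 or rj > 0:
        if state == "M":
            path.append((ri - 1, rj - 1))
            state = pick(
                [
                    ("M", M[ri - 1, rj - 1]),
                    ("GA", GA[ri - 1, rj - 1]),
                    ("GB", GB[ri - 1, rj - 1]),
                ]
            )
            ri -= 1
            rj -= 1
        elif state == "GA":
            path.append((ri - 1, -1))
            state = pick(
                [
                    ("M", M[ri - 1, rj] - go),
                    ("GA", GA[ri - 1, rj] - ge),
                    ("GB", GB[ri - 1, rj] - go),
                ]
            )
            ri -= 1
        else:  # GB
            path.append((-1, rj - 1))
            state = pick(
                [
                    ("M", M[ri, rj - 1] - go),
                    ("GA", GA[ri, rj - 1] - go),
                    ("GB", GB[ri, rj - 1] - ge),
                ]
            )
            rj -= 1
        if ri == 0 and rj == 0:
            break
    path.reverse()
    return path, float(score)


def _merge(pa: _Profile, pb: _Profile, path: list[tuple[int, int]]) -> _Profile:
    rows_a = ["".join(r[ia] if ia >= 0 else GAP for ia, _ in path) for r in pa.rows]
    rows_b = ["".join(r[ib] if ib >= 0 else GAP for _, ib in path) for r in pb.rows]
    return _Profile(pa.ids + pb.ids, rows_a + rows_b)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def align_protein_pair(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment of two amino-acid strings."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    S = _BLOSUM62 if matrix is None else matrix
    pa, pb = _Profile(["a"], [a]), _Profile(["b"], [b])
    path, score = _nw_profiles(pa, pb, S, gap_open, gap_extend)
    merged = _merge(pa, pb, path)
    return PairwiseAlignment(a=merged.rows[0], b=merged.rows[1], score=score)


def backtranslate(
    protein_alignment: MultipleAlignment,
    codon_seqs: Mapping[str, str],
    code: GeneticCode = DEFAULT_CODE,
) -> MultipleAlignment:
    """Expand a protein alignment to codons; protein gaps become ``---``.

    Each codon sequence (trailing partial codon trimmed) must translate to
    its degapped protein row.
    """
    out: list[str] = []
    for idx, seq_id in enumerate(protein_alignment.ids):
        if seq_id not in codon_seqs:
            raise ValueError(f"no codon sequence provided for {seq_id!r}")
        nt = codon_seqs[seq_id].upper()
        nt = nt[: len(nt) - len(nt) % 3]
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            prot = translate(nt, code)
        # stops are carried as X through alignment (BLOSUM has no '*')
        prot = prot.replace("*", "X")
        gapped = protein_alignment.seqs[idx]
        degapped = gapped.replace(GAP, "")
        if prot != degapped:
            for pos, (x, y) in enumerate(zip(prot, degapped)):
                if x != y:
                    raise ValueError(
                        f"{seq_id}: protein/codon mismatch at residue {pos + 1} "
                        f"({y!r} in alignment vs {x!r} translated)"
                    )
            raise ValueError(
                f"{seq_id}: protein length {len(degapped)} does not match "
                f"{len(prot)} translated codons"
            )
        pieces: list[str] = []
        k = 0
        for ch in gapped:
            if ch == GAP:
                pieces.append("---")
            else:
                pieces.append(nt[3 * k: 3 * k + 3])
                k += 1
        out.append("".join(pieces))
    return MultipleAlignment(
        ids=protein_alignment.ids, seqs=tuple(out), alphabet="codon"
    )


def _protein_p_distance(aln: PairwiseAlignment) -> float:
    diffs = compared = 0
    for x, y in zip(aln.a, aln.b):
        if x == GAP or y == GAP or "X" in (x, y):
            continue
        compared += 1
        diffs += x != y
    return diffs / compared if compared else 0.0


def progressive_align(
    seqs: Mapping[str, str],
    code: GeneticCode = DEFAULT_CODE,
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MultipleAlignment:
    """Codon-aware multiple alignment of named codon sequences.

    Output row order matches input order. With two inputs this reduces to
    ``align_protein_pair`` + ``backtranslate``.
    """
    import warnings as _w

    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least two sequences")
    S = _BLOSUM62 if matrix is None else matrix
    ids = list(seqs)
    trimmed = {k: v.upper()[: len(v) - len(v) % 3] for k, v in seqs.items()}
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        prots = {k: translate(v, code) for k, v in trimmed.items()}
    for k, p in prots.items():
        if not p:
            raise ValueError(f"{k}: sequence shorter than one codon")
    # stops are aligned as X (BLOSUM has no '*')
    prots = {k: p.replace("*", "X") for k, p in prots.items()}

    if len(ids) == 2:
        pa = align_protein_pair(prots[ids[0]], prots[ids[1]], S, gap_open, gap_extend)
        prot_aln = MultipleAlignment(
            ids=tuple(ids), seqs=(pa.a, pa.b), alphabet="protein"
        )
        return backtranslate(prot_aln, trimmed, code)

    # guide tree from pairwise protein p-distances
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa = align_protein_pair(prots[ids[i]], prots[ids[j]], S, gap_open, gap_extend)
            D[i, j] = D[j, i] = _protein_p_distance(pa)
    guide = nj_tree(DistanceMatrix(ids=ids, values=D))

    profiles: dict[tuple[str, ...], _Profile] = {
        (sid,): _Profile([sid], [prots[sid]]) for sid in ids
    }
    current: tuple[str, ...] = (ids[0],)
    for left, right in guide.merge_order():
        pa_, pb_ = profiles.pop(left), profiles.pop(right)
        path, _ = _nw_profiles(pa_, pb_, S, gap_open, gap_extend)
        merged = _merge(pa_, pb_, path)
        key = left + right
        profiles[key] = merged
        current = key
    final = profiles[current]
    order = {sid: final.rows[final.ids.index(sid)] for sid in ids}
    prot_aln = MultipleAlignment(
        ids=tuple(ids), seqs=tuple(order[sid] for sid in ids), alphabet="protein"
    )
    return backtranslate(prot_aln, trimmed, code)
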