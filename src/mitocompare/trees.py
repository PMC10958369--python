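"""Neighbor-joining trees, splits, and monophyly tests.

NJ here is the package's internal sanity check on distance matrices (and
the guide-tree engine for progressive alignment); likelihood and Bayesian
inference are exported to external tools, never reimplemented. The
implementation is canonical Saitou–Nei NJ with two determinism rules:

* ties in the Q criterion are broken by the first (i, j) pair in index
  order, with input taxa previously sorted nowhere — callers get the
  order they supplied;
* negative branch lengths are clamped to zero and the deficit moved onto
  the sister branch, so total path lengths between taxa are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

__all__ = ["TreeNode", "PhyloTree", "DistanceMatrix", "nj_tree", "is_monophyletic"]


@dataclass
class TreeNode:
    name: str | None = None                       # leaf label; None internal
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        if self.is_leaf:
            return self.name or ""
        inner = ",".join(
            f"{child.newick()}:{length:.6f}" for child, length in self.children
        )
        return f"({inner})"


@dataclass
class PhyloTree:
    """An (unrooted, stored with an arbitrary trifurcating root) phylogeny."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def newick(self) -> str:
        return self.root.newick() + ";"

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each normalized to the side that does
        not contain the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                out.add(side)
            return below

        for child, _ in self.root.children:
            walk(child)
        return out

    def merge_order(self) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
        """Postorder list of (left leafset, right leafset) joins — the
        schedule a progressive aligner follows."""
        order: list[tuple[tuple[str, ...], tuple[str, ...]]] = []

        def walk(node: TreeNode) -> tuple[str, ...]:
            if node.is_leaf:
                return (node.name,)  # type: ignore[return-value]
            parts = [walk(c) for c, _ in node.children]
            acc = parts[0]
            for nxt in parts[1:]:
                order.append((acc, nxt))
                acc = acc + nxt
            return acc

        walk(self.root)
        return order


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with NaN marking undefined entries."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T)
        ):
            raise ValueError("distance matrix is not symmetric")

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, j in combinations(range(len(self.ids)), 2):
            if np.isnan(self.values[i, j]):
                out.append((self.ids[i], self.ids[j]))
        return out


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp negatives to 0, transferring the deficit to the sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor-joining.

    Raises on undefined (NaN) entries, listing the offending pairs. On an
    additive matrix the generating topology is recovered exactly.
    """
    bad = dm.undefined_pairs()
    if bad:
        raise ValueError(f"distance matrix has undefined entries: {bad}")
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    D = dm.values.astype(float).copy()
    active = list(range(n))

    if n == 2:
        half = D[0, 1] / 2.0
        root = TreeNode(children=[(nodes[0], half), (nodes[1], half)])
        return PhyloTree(root=root)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_q = np.inf
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (a, b)
        a, b = best  # type: ignore[misc]
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remainder
        new_row = np.zeros(D.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = (D[i, k] + D[j, k] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    # final three-way join (three-point formulas)
    i, j, k = active
    la = (D[i, j] + D[i, k] - D[j, k]) / 2.0
    lb = (D[i, j] + D[j, k] - D[i, k]) / 2.0
    lc = (D[i, k] + D[j, k] - D[i, j]) / 2.0
    lens = [la, lb, lc]
    for idx in range(3):
        if lens[idx] < 0:
            # move the deficit to the longest remaining branch
            other = max((o for o in range(3) if o != idx), key=lambda o: lens[o])
            lens[other] += lens[idx]
            lens[idx] = 0.0
    lens = [max(x, 0.0) for x in lens]
    root = TreeNode(
        children=[(nodes[i], lens[0]), (nodes[j], lens[1]), (nodes[k], lens[2])]
    )
    return PhyloTree(root=root)


def is_monophyletic(tree: PhyloTree, taxa: Iterable[str]) -> bool:
    """Whether ``taxa`` form one side of a split of the unrooted tree.

    Trivial groups (single taxon, all taxa) are monophyletic by
    convention. Unknown taxon names raise.
    """
    subset = frozenset(taxa)
    all_leaves = frozenset(tree.leaf_names())
    unknown = subset - all_leaves
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    if len(subset) <= 1 or subset == all_leaves or len(subset) == len(all_leaves) - 1:
        return True
    ref = min(all_leaves)
    side = subset if ref not in subset else all_leaves - subset
    return side in tree.splits()


def path_length_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths (the additive matrix of the tree)."""
    names = tree.leaf_names()
    index = {n: i for i, n in enumerate(names)}
    n = len(names)
    D = np.zeros((n, n))

    def walk(node: TreeNode, dist0: dict[str, float]) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}  # type: ignore[dict-item]
        sides = []
        for child, length in node.children:
            below = walk(child, dist0)
            sides.append({k: v + length for k, v in below.items()})
        for x, y in combinations(sides, 2):
            for nx, dx in x.items():
                for ny, dy in y.items():
                    D[index[nx], index[ny]] = D[index[ny], index[nx]] = dx + dy
        merged: dict[str, float] = {}
        for s in sides:
            merged.update(s)
        return merged

    walk(tree.root, {})
    return DistanceMatrix(ids=names, values=D)
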