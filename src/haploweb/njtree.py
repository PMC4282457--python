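"""Neighbour-joining trees and column-resampling bootstrap supports.

Distances are K2P with pairwise deletion (see seq_core); the
agglomeration is the classic Saitou–Nei / Studier–Keppler neighbour
joining. Negative branch-length estimates, which NJ can produce when the
input is not additive, are clamped to zero with the deficit moved to the
sister branch, so path lengths between the joined pair are preserved.

Bootstrap supports resample alignment columns with replacement, rebuild
the NJ tree each time, and report for each taxon group the percentage of
replicates in which that group forms one side of a tree bipartition.
Singleton groups and the full taxon set are trivially present in every
tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np

from .seq_core import Alignment, DistanceMatrix, distance_matrix

__all__ = ["TreeNode", "Tree", "build_nj_tree", "bootstrap_supports"]


@dataclass
class TreeNode:
    """Node of an (unrooted, arbitrarily anchored) phylogenetic tree."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def tip_names(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset({self.name} if self.name else set())
        out: set[str] = set()
        for c in self.children:
            out |= c.tip_names()
        return frozenset(out)

    def _newick(self) -> str:
        length = self.length + 0.0  # normalizes IEEE negative zero
        if self.is_leaf:
            return f"{self.name}:{length:.6g}"
        inner = ",".join(c._newick() for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}:{length:.6g}"


@dataclass
class Tree:
    """Unrooted tree anchored at a trifurcating (or bifurcating) root node."""

    root: TreeNode

    def tips(self) -> frozenset[str]:
        return self.root.tip_names()

    def newick(self) -> str:
        inner = ",".join(c._newick() for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the tip set on one side of an edge."""
        all_tips = self.tips()
        out: set[frozenset[str]] = set()

        def visit(node: TreeNode) -> None:
            for c in node.children:
                tips = c.tip_names()
                if 1 < len(tips) < len(all_tips) - 1:
                    out.add(tips)
                visit(c)

        visit(self.root)
        return out

    def has_group(self, group: frozenset[str]) -> bool:
        """Whether `group` is one side of some bipartition (or trivial)."""
        all_tips = self.tips()
        if not group <= all_tips:
            raise ValueError("group contains taxa absent from the tree")
        if len(group) <= 1 or len(group) >= len(all_tips) - 1:
            return True
        return group in self.bipartitions() or (all_tips - group) in self.bipartitions()


def _nj_merge_order(d: np.ndarray) -> list[tuple[int, int, float, float]]:
    """Run NJ on a working copy; yields (i, j, li, lj) merges over live indices."""
    n = d.shape[0]
    active = list(range(n))
    d = d.copy()
    merges: list[tuple[int, int, float, float]] = []
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest flat index
        i_, j_ = np.unravel_index(int(np.argmin(q)), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dab = sub[i_, j_]
        li = 0.5 * dab + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dab - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        # distances from the new node u to every other active node
        for k_, c in enumerate(active):
            if c in (a, b):
                continue
            d[a, c] = d[c, a] = 0.5 * (sub[i_, k_] + sub[j_, k_] - dab)
        merges.append((a, b, li, lj))
        active.remove(b)
    if len(active) == 2:
        a, b = active
        merges.append((a, b, d[a, b], np.nan))
    return merges


def build_nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbour-joining tree from a distance matrix.

    Requires >= 3 taxa and finite distances; a saturated pair is reported
    by id. The returned tree is unrooted, anchored at the last join.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError(f"neighbour joining needs >= 3 taxa, got {n}")
    if dm.any_saturated:
        pair = dm.saturated_pairs()[0]
        raise ValueError(
            f"saturated distance between {pair[0]!r} and {pair[1]!r}"
        )
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=dm.ids[i]) for i in range(n)
    }
    merges = _nj_merge_order(dm.d)
    for a, b, li, lj in merges[:-1]:
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = li, lj
        nodes[a] = TreeNode(children=[na, nb])
    a, b, dab, _ = merges[-1]
    na, nb = nodes.pop(a), nodes.pop(b)
    if na.is_leaf and not nb.is_leaf:
        na, nb = nb, na  # anchor at an internal node when possible
    na.length = 0.0
    nb.length = max(dab, 0.0)
    root = na if not na.is_leaf else TreeNode(children=[na, nb])
    if root is na:
        root.children.append(nb)
    return Tree(root=root)


def bootstrap_supports(
    aln: Alignment,
    groups: TypingSequence[Iterable[str]],
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support (percent) for each taxon group.

    Each replicate resamples alignment columns with replacement, recomputes
    the K2P distance matrix and NJ tree, and checks whether the group is a
    bipartition of that tree. Replicates in which a resampled distance
    saturates are counted as not supporting the group.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    taxa = frozenset(aln.ids)
    fgroups = [frozenset(g) for g in groups]
    for g in fgroups:
        if not g <= taxa:
            raise ValueError(f"group {sorted(g)} not a subset of alignment taxa")
    enc = aln.encoded()
    L = aln.length
    hits = {g: 0 for g in fgroups}
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        try:
            dm = distance_matrix(aln, enc=enc[:, cols])
            tree = build_nj_tree(dm)
        except ValueError:
            continue
        parts = tree.bipartitions()
        for g in fgroups:
            if len(g) <= 1 or len(g) >= len(taxa) - 1:
                hits[g] += 1
            elif g in parts or (taxa - g) in parts:
                hits[g] += 1
    return {g: 100.0 * hits[g] / B for g in fgroups}


def supports_by_label(
    supports: Mapping[frozenset[str], float],
    labels: Mapping[frozenset[str], str],
) -> dict[str, float]:
    """Re-key a support table by human-readable group labels."""
    return {labels[g]: v for g, v in supports.items() if g in labels}
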