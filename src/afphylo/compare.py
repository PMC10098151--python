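"""Tree comparison: bipartitions, Robinson–Foulds symmetric difference, and
relative accuracy against a reference method.

Every internal edge of an unrooted tree splits the leaves into two blocks;
two trees over the same leaves are compared by how many of these nontrivial
splits occur in exactly one of them (the RF symmetric difference).  Rooted
trees are implicitly unrooted: the two edges meeting at a bifurcating root
induce the same split, and duplicates collapse in the set representation.
"""

from __future__ import annotations

import math
import warnings
from typing import FrozenSet, Set

import dendropy

from .errors import LabelError

__all__ = ["bipartitions", "rf_distance", "relative_accuracy"]

Bipartition = FrozenSet[str]


def bipartitions(tree: dendropy.Tree) -> Set[Bipartition]:
    """Canonical nontrivial bipartitions of a tree.

    Each split is represented by the block *not* containing the pivot leaf
    (the lexicographically smallest label), as a frozenset.  Trivial splits
    (a singleton on either side) are excluded, so a fully resolved unrooted
    tree on n leaves yields exactly n-3 bipartitions.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise LabelError("tree has duplicate leaf labels")
    full = frozenset(labels)
    n = len(labels)
    pivot = min(labels)

    below: dict[int, FrozenSet[str]] = {}
    splits: Set[Bipartition] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            continue
        leafset = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = leafset
        if node.parent_node is None:
            continue
        block = full - leafset if pivot in leafset else leafset
        if 2 <= len(block) <= n - 2:
            splits.add(block)
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds symmetric difference |B1 Δ B2| over nontrivial
    bipartitions; both trees are treated as unrooted."""
    b1 = bipartitions(t1)
    b2 = bipartitions(t2)
    l1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    l2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if l1 != l2:
        missing = sorted(l1 ^ l2)
        raise LabelError(f"leaf label sets differ between trees: {missing}")
    return len(b1 ^ b2)


def relative_accuracy(rf_target: int, rf_reference: int) -> float:
    """Accuracy of a target method relative to a reference method, both
    scored by RF symmetric difference against the same truth tree.

    Returns ``rf_reference / rf_target`` so that values > 1 mean the target
    is closer to the truth than the reference (the reference itself scores
    exactly 1).  A perfect target against an imperfect reference yields
    infinity (flagged with a warning); two perfect methods score 1.
    """
    if rf_target < 0 or rf_reference < 0:
        raise ValueError("RF distances are nonnegative")
    if rf_target == 0:
        if rf_reference == 0:
            return 1.0
        warnings.warn(
            "target tree matches the truth exactly (RF = 0); "
            "relative accuracy is infinite",
            stacklevel=2,
        )
        return math.inf
    return rf_reference / rf_target
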