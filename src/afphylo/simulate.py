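"""Simulation of random trees and sequences evolved along them.

The generator stands in for curated benchmark data: it draws a random binary
topology, assigns branch lengths, places an i.i.d. uniform root sequence and
evolves it to the leaves under an equal-rates (Jukes–Cantor) substitution
model, where a branch of length t (expected substitutions per site) changes
each site to a uniformly chosen *different* base with probability

    p(t) = 3/4 * (1 - exp(-4 t / 3))

No indels and no rate heterogeneity: leaves stay positionally comparable, so
the alignment-free measures are exercised on pure substitution divergence.
All randomness flows from the single seed passed in; no global state.
"""

from __future__ import annotations

import math
from typing import List, Optional, Tuple

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .errors import ParameterError
from .sequence_io import Sequence

__all__ = [
    "jc_substitution_probability",
    "random_tree",
    "random_clock_tree",
    "evolve",
    "cophenetic_matrix",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def jc_substitution_probability(t: float) -> float:
    """Per-site probability of an observable change over a branch of length
    t expected substitutions/site, under equal rates."""
    if t < 0:
        raise ParameterError("branch length must be nonnegative")
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def _default_labels(n: int) -> List[str]:
    width = len(str(n))
    return [f"t{i + 1:0{width}d}" for i in range(n)]


def random_tree(
    n_leaves: int,
    seed: int,
    branch_length_range: Tuple[float, float] = (0.1, 2.0),
    labels: Optional[List[str]] = None,
) -> dendropy.Tree:
    """Random rooted binary topology by sequential random joins, with branch
    lengths drawn uniformly from ``branch_length_range``."""
    if n_leaves < 3:
        raise ParameterError("need at least 3 leaves for a tree")
    lo, hi = branch_length_range
    if lo < 0 or hi < lo:
        raise ParameterError(f"bad branch length range {branch_length_range!r}")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = _default_labels(n_leaves)
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(lo, hi))
        nodes = [nodes[x] for x in range(len(nodes)) if x not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def random_clock_tree(
    n_leaves: int,
    seed: int,
    height_increment_range: Tuple[float, float] = (0.1, 1.0),
    labels: Optional[List[str]] = None,
) -> dendropy.Tree:
    """Random ultrametric (molecular-clock) tree: clusters merge at strictly
    increasing heights, so all leaves are equidistant from the root."""
    if n_leaves < 3:
        raise ParameterError("need at least 3 leaves for a tree")
    lo, hi = height_increment_range
    if lo <= 0 or hi < lo:
        raise ParameterError(f"bad height increment range {height_increment_range!r}")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = _default_labels(n_leaves)
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    heights = [0.0] * n_leaves
    h = 0.0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        h += float(rng.uniform(lo, hi))
        parent = dendropy.Node()
        for child_idx in (i, j):
            child = nodes[child_idx]
            parent.add_child(child)
            child.edge.length = h - heights[child_idx]
        keep = [x for x in range(len(nodes)) if x not in (i, j)]
        nodes = [nodes[x] for x in keep] + [parent]
        heights = [heights[x] for x in keep] + [h]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def evolve(tree: dendropy.Tree, root_length: int, seed: int) -> List[Sequence]:
    """Evolve an i.i.d. uniform root sequence down the tree; returns one
    validated :class:`Sequence` per leaf, in leaf-traversal order."""
    if root_length < 1:
        raise ParameterError("root sequence length must be >= 1")
    rng = np.random.default_rng(seed)
    root_codes = rng.integers(0, 4, size=root_length, dtype=np.int8)
    codes: dict[int, np.ndarray] = {id(tree.seed_node): root_codes}
    out: List[Sequence] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            parent_codes = codes[id(node.parent_node)]
            t = node.edge.length if node.edge.length is not None else 0.0
            p = jc_substitution_probability(t)
            seq_codes = parent_codes.copy()
            hit = np.nonzero(rng.random(root_length) < p)[0]
            if hit.size:
                # shift by 1..3 mod 4: always a different base
                seq_codes[hit] = (
                    seq_codes[hit] + rng.integers(1, 4, size=hit.size, dtype=np.int8)
                ) % 4
            codes[id(node)] = seq_codes
        if node.is_leaf():
            residues = _BASES[codes[id(node)]].tobytes().decode("ascii")
            out.append(Sequence(id=node.taxon.label, residues=residues))
    return out


def cophenetic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distance matrix, labels in leaf
    traversal order."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = [leaf.taxon for leaf in tree.leaf_node_iter()]
    n = len(leaves)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i], leaves[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=[t.label for t in leaves], values=values)
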