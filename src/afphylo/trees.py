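"""Distance-based tree building: UPGMA and neighbor joining.

Trees are held as :class:`dendropy.Tree` objects.  UPGMA produces a rooted
ultrametric tree (every leaf equidistant from the root); NJ produces an
unrooted tree represented with a trifurcating root.

Determinism: when two pairs tie on the merge criterion (minimum distance for
UPGMA, minimum Q for NJ) the lexicographically smallest (i, j) index pair in
the current matrix ordering wins, so runs are bit-reproducible.
"""

from __future__ import annotations

import re
from typing import List, Tuple

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .errors import MatrixError, ParameterError

__all__ = ["upgma", "nj", "to_newick", "parse_newick", "leaf_labels"]


def _validated(dm: DistanceMatrix) -> np.ndarray:
    dm.validate()
    if len(dm.labels) < 2:
        raise ParameterError("tree building needs at least 2 taxa")
    # symmetrise exactly so tie-breaking is stable
    v = dm.values.astype(float)
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    return v


def _leaves(labels: List[str], tns: dendropy.TaxonNamespace) -> List[dendropy.Node]:
    nodes = []
    for lab in labels:
        taxon = tns.get_taxon(lab)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    return nodes


def _argmin_pair(m: np.ndarray) -> Tuple[int, int]:
    """First (row-major) position of the minimum above the diagonal —
    i.e. the lexicographically smallest tying (i, j) with i < j."""
    work = m.copy()
    il = np.tril_indices_from(work)
    work[il] = np.inf
    flat = int(np.argmin(work))
    return divmod(flat, work.shape[0])


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Unweighted pair-group agglomeration with arithmetic-mean linkage.

    The closest pair of clusters is merged at height d_min/2; the distance
    from the merged cluster to any other is the size-weighted mean of its
    members' distances, so every original pair contributes equally.
    """
    D = _validated(dm)
    tns = dendropy.TaxonNamespace(dm.labels)
    nodes = _leaves(dm.labels, tns)
    heights = [0.0] * len(nodes)
    sizes = [1] * len(nodes)

    while len(nodes) > 1:
        i, j = _argmin_pair(D)
        h = D[i, j] / 2.0
        parent = dendropy.Node()
        for child_idx in (i, j):
            child = nodes[child_idx]
            parent.add_child(child)
            child.edge.length = h - heights[child_idx]
        si, sj = sizes[i], sizes[j]
        new_row = (si * D[i, :] + sj * D[j, :]) / (si + sj)
        keep = [x for x in range(len(nodes)) if x not in (i, j)]
        D = D[np.ix_(keep, keep)]
        new_row = new_row[keep]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row
        D[:-1, -1] = new_row
        nodes = [nodes[x] for x in keep] + [parent]
        heights = [heights[x] for x in keep] + [h]
        sizes = [sizes[x] for x in keep] + [si + sj]

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def _clamp_pair(li: float, lj: float, d_ij: float) -> Tuple[float, float]:
    # negative limb: clamp to 0, move the deficit onto the sibling branch
    if li < 0.0:
        return 0.0, d_ij
    if lj < 0.0:
        return d_ij, 0.0
    return li, lj


def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Joins the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j, assigns limb
    lengths by the standard formulas, and reduces the matrix with
    d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2.  Exact on additive matrices.
    Terminates with a trifurcating root joining the last three clusters; for
    two taxa it degrades to a single cherry.
    """
    D = _validated(dm)
    tns = dendropy.TaxonNamespace(dm.labels)
    nodes = _leaves(dm.labels, tns)

    if len(nodes) == 2:
        root = dendropy.Node()
        half = D[0, 1] / 2.0
        for node in nodes:
            root.add_child(node)
            node.edge.length = half
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        tree.is_rooted = False
        return tree

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        i, j = _argmin_pair(Q)
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d_ij - li
        li, lj = _clamp_pair(li, lj, d_ij)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_row = (D[i, :] + D[j, :] - d_ij) / 2.0
        keep = [x for x in range(n) if x not in (i, j)]
        D = D[np.ix_(keep, keep)]
        new_row = new_row[keep]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row
        D[:-1, -1] = new_row
        nodes = [nodes[x] for x in keep] + [parent]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    limbs = [
        max(0.0, 0.5 * (d01 + d02 - d12)),
        max(0.0, 0.5 * (d01 + d12 - d02)),
        max(0.0, 0.5 * (d02 + d12 - d01)),
    ]
    root = dendropy.Node()
    for node, limb in zip(nodes, limbs):
        root.add_child(node)
        node.edge.length = limb
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,']")


def _format_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_node(node: dendropy.Node) -> str:
    if node.is_leaf():
        s = _format_label(node.taxon.label if node.taxon else "")
    else:
        s = "(" + ",".join(_format_node(c) for c in node.child_nodes()) + ")"
    if node.parent_node is not None and node.edge.length is not None:
        s += f":{node.edge.length:.10g}"
    return s


def to_newick(tree: dendropy.Tree) -> str:
    """Serialise with branch lengths at 10 significant digits; labels with
    whitespace or Newick metacharacters are single-quoted."""
    return _format_node(tree.seed_node) + ";"


def parse_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string (underscores preserved verbatim in labels)."""
    return dendropy.Tree.get(
        data=source, schema="newick", preserve_underscores=True
    )


def leaf_labels(tree: dendropy.Tree) -> List[str]:
    """Leaf taxon labels in tree traversal order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
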