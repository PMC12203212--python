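"""Tree comparison and characterisation metrics.

Quartet similarity is computed by brute-force enumeration of all C(n, 4)
leaf subsets — tractable at desk scale and self-evidently correct, so the
same code doubles as its own oracle. Ultrametricity (dispersion of
root-to-leaf path lengths) and reference congruence (fraction of
reference-resolved quartets matched) are explicitly surrogates for the
FoldTree metrics of the same intent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np


@dataclass(frozen=True)
class QuartetResult:
    n_quartets: int
    n_agree: int

    @property
    def similarity(self) -> float:
        return self.n_agree / self.n_quartets if self.n_quartets else 0.0


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def _topo_distances(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Pairwise path lengths in edge counts between the given leaves."""
    adj: dict = {}
    leaf_of: dict[str, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(node, [])
        for child in node.child_nodes():
            adj[node].append(child)
            adj.setdefault(child, []).append(node)
        if node.is_leaf() and node.taxon is not None:
            leaf_of[node.taxon.label] = node
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n), dtype=np.int64)
    for lab in labels:
        start = leaf_of[lab]
        depth = {start: 0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in depth:
                    depth[v] = depth[u] + 1
                    stack.append(v)
        i = pos[lab]
        for other in labels:
            D[i, pos[other]] = depth[leaf_of[other]]
    return D


def _assert_resolved(tree: dendropy.Tree, name: str) -> None:
    """A resolved tree has no node of degree > 3 (root of degree 2 allowed)."""
    for node in tree.preorder_node_iter():
        degree = len(node.child_nodes()) + (
            0 if node.parent_node is None else 1
        )
        if degree > 3:
            raise ValueError(f"{name} is not fully resolved")


def _quartet_codes(D: np.ndarray, quartets: np.ndarray) -> np.ndarray:
    """Topology code per quartet from the four-point condition.

    For leaves (a, b, c, d) the pairing with the strictly smallest distance
    sum is the induced split: 0 = ab|cd, 1 = ac|bd, 2 = ad|bc, -1 =
    unresolved (no strict minimum — happens only at polytomies).
    """
    a, b, c, d = quartets.T
    sums = np.stack([
        D[a, b] + D[c, d],
        D[a, c] + D[b, d],
        D[a, d] + D[b, c],
    ], axis=1)
    order = np.argsort(sums, axis=1)
    smallest = np.take_along_axis(sums, order[:, :1], axis=1)[:, 0]
    second = np.take_along_axis(sums, order[:, 1:2], axis=1)[:, 0]
    codes = order[:, 0].astype(np.int64)
    codes[smallest == second] = -1
    return codes


def quartet_similarity(
    t1: dendropy.Tree, t2: dendropy.Tree
) -> QuartetResult:
    """Fraction of 4-leaf subsets with identical induced topologies.

    Both trees must be fully resolved and share the same leaf set
    (mismatches are reported). O(n^4) enumeration.
    """
    l1, l2 = _leaf_labels(t1), _leaf_labels(t2)
    if l1 != l2:
        diff = sorted(l1 ^ l2)
        raise ValueError(f"leaf sets differ: {diff}")
    _assert_resolved(t1, "t1")
    _assert_resolved(t2, "t2")
    labels = sorted(l1)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 shared leaves")
    D1 = _topo_distances(t1, labels)
    D2 = _topo_distances(t2, labels)
    quartets = np.array(list(combinations(range(n), 4)), dtype=np.int64)
    c1 = _quartet_codes(D1, quartets)
    c2 = _quartet_codes(D2, quartets)
    agree = int(((c1 == c2) & (c1 >= 0)).sum())
    return QuartetResult(len(quartets), agree)


def ultrametricity(tree: dendropy.Tree) -> float:
    """Coefficient of variation of root-to-leaf path lengths.

    0 for a perfectly clocklike tree; invariant under uniform branch
    scaling. Requires a rooted tree with branch lengths.
    """
    if not tree.is_rooted:
        raise ValueError("ultrametricity requires a rooted tree")
    depths = []
    def walk(node, depth):
        if node.is_leaf():
            depths.append(depth)
            return
        for child in node.child_nodes():
            walk(child, depth + (child.edge.length or 0.0))
    walk(tree.seed_node, 0.0)
    arr = np.asarray(depths)
    mean = arr.mean()
    if mean == 0:
        return 0.0
    return float(arr.std() / mean)


def mean_branch_length(tree: dendropy.Tree) -> float:
    """Arithmetic mean over all branches (internal and terminal)."""
    lengths = [
        (node.edge.length or 0.0)
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    ]
    if not lengths:
        raise ValueError("tree has no branches")
    return float(np.mean(lengths))


def reference_congruence(
    tree: dendropy.Tree, reference: dendropy.Tree
) -> float:
    """Fraction of reference-resolved quartets the tree reproduces.

    The reference may be multifurcating (e.g. a taxonomy); quartets it
    leaves unresolved are excluded from the denominator. The tree's leaves
    must be a subset of the reference's. An entirely unresolved reference
    (no resolved quartet) is an error.
    """
    lt, lr = _leaf_labels(tree), _leaf_labels(reference)
    if not lt <= lr:
        raise ValueError(f"tree leaves missing from reference: {sorted(lt - lr)}")
    labels = sorted(lt)
    if len(labels) < 4:
        raise ValueError("need at least 4 leaves")
    Dt = _topo_distances(tree, labels)
    Dr = _topo_distances(reference, labels)
    quartets = np.array(list(combinations(range(len(labels)), 4)),
                        dtype=np.int64)
    ct = _quartet_codes(Dt, quartets)
    cr = _quartet_codes(Dr, quartets)
    resolved = cr >= 0
    if not resolved.any():
        raise ValueError("reference resolves no quartets")
    return float((ct[resolved] == cr[resolved]).sum() / resolved.sum())
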