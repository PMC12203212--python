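"""Tree inference: distances, neighbor joining, bootstrap, MAD rooting.

The built-in tree builder is distance-based neighbor joining on
Poisson-corrected amino-acid distances; maximum-likelihood inference remains
the job of external tools (IQ-TREE / FastTree / RAxML-NG), reachable through
:func:`run_external_tree`. Trees are ``dendropy.Tree`` objects throughout;
support values are stored as internal-node labels.

Rooting follows the minimal ancestor deviation (MAD) criterion: for every
branch the root position minimising the root-mean-square relative deviation
of ancestor distances from the clocklike expectation is evaluated in closed
form (the squared deviation is exactly quadratic along a branch), and the
best branch wins.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_D_MAX = 3.0  # Poisson distance cap, = -ln(1 - 0.95)


# ---------------------------------------------------------------------------
# distances


def _encode_rows(msa: dict[str, str]) -> tuple[list[str], np.ndarray]:
    species = sorted(msa)
    L = {len(v) for v in msa.values()}
    if len(L) != 1:
        raise ValueError("alignment rows have unequal lengths")
    mat = np.frombuffer(
        "".join(msa[sp] for sp in species).encode("ascii"), dtype=np.uint8
    ).reshape(len(species), L.pop())
    return species, mat


def pairwise_distance(msa: dict[str, str]) -> pd.DataFrame:
    """Poisson-corrected AA distance matrix from an alignment.

    ``d = -ln(1 - p)`` with ``p`` the mismatch fraction over columns where
    both rows carry an unambiguous residue (gaps and 'X' are skipped).
    ``p >= 0.95`` is clamped to ``d = 3.0`` with a warning. A pair with no
    overlapping columns is an error.
    """
    species, mat = _encode_rows(msa)
    if len(species) < 3:
        raise ValueError("need at least 3 species")
    valid = (mat != ord("-")) & (mat != ord("X"))
    n = len(species)
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        n_cols = int(both.sum())
        if n_cols == 0:
            raise ValueError(
                f"no overlapping columns between {species[i]!r} and "
                f"{species[j]!r}"
            )
        p = float((mat[i, both] != mat[j, both]).sum()) / n_cols
        if p >= 0.95:
            logger.warning(
                "saturated distance between %s and %s (p=%.2f); clamped to "
                "%.1f", species[i], species[j], p, _D_MAX,
            )
            d = _D_MAX
        else:
            d = -math.log(1.0 - p)
        D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=species, columns=species)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Canonical Saitou-Nei neighbor joining.

    Deterministic: taxa are processed in sorted-label order and Q-matrix
    ties resolve to the first (smallest-index) pair. Negative branch lengths
    are clamped to 0. Returns an unrooted tree (trifurcating seed node).
    """
    labels = list(dist.index)
    if list(dist.columns) != labels:
        raise ValueError("distance matrix index/columns mismatch")
    D0 = dist.to_numpy(dtype=float)
    if not np.allclose(D0, D0.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    labels = [labels[i] for i in order]
    D0 = D0[np.ix_(order, order)]
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)

    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = D0
    active = list(range(n))
    next_id = n
    while len(active) > 3:
        na = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = divmod(int(np.argmin(Q)), na)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (na - 2))
        lj = dij - li
        li, lj = max(0.0, li), max(0.0, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes.append(parent)
        for k in active:
            if k not in (i, j):
                D[next_id, k] = D[k, next_id] = 0.5 * (
                    D[i, k] + D[j, k] - dij
                )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # final three nodes joined at the unrooted seed
    a, b, c = active
    seed = dendropy.Node()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        length = 0.5 * (D[x, y] + D[x, z] - D[y, z])
        seed.add_child(nodes[x])
        nodes[x].edge.length = max(0.0, length)
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Edge]:
    """Non-trivial splits as canonical frozensets of leaf labels."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: dict[frozenset, dendropy.Edge] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        other = leaves - side
        key = side if sorted(side)[0] < sorted(other)[0] else other
        out[key] = node
    return out


def bootstrap_support(
    msa: dict[str, str],
    n_reps: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with classical Felsenstein bootstrap support.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal split of the full-alignment tree is the percentage of
    replicate NJ trees containing it, written as the internal node label.
    With ``n_reps=0`` the tree is returned without support values.
    """
    tree = nj_tree(pairwise_distance(msa))
    if n_reps <= 0:
        return tree
    species, mat = _encode_rows(msa)
    rng = np.random.default_rng(seed)
    n_cols = mat.shape[1]
    counts: dict[frozenset, int] = {}
    splits = _bipartitions(tree)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        sub = {sp: row for sp, row in zip(
            species,
            ("".join(map(chr, mat[i, cols])) for i in range(len(species))),
        )}
        try:
            rep_tree = nj_tree(pairwise_distance(sub))
        except ValueError:
            continue  # e.g. a replicate with no overlap for some pair
        for key in _bipartitions(rep_tree):
            if key in splits:
                counts[key] = counts.get(key, 0) + 1
    for key, node in splits.items():
        pct = 100.0 * counts.get(key, 0) / n_reps
        node.label = f"{pct:.0f}"
    return tree


# ---------------------------------------------------------------------------
# MAD rooting


def _adjacency(tree: dendropy.Tree):
    """Undirected (node -> [(neighbor, length)]) view of a dendropy tree."""
    adj: dict[dendropy.Node, list] = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(node, [])
        for child in node.child_nodes():
            ln = child.edge.length or 0.0
            adj[node].append((child, ln))
            adj.setdefault(child, []).append((node, ln))
    return adj


def _dist_from(start, adj) -> dict:
    out = {start: 0.0}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, ln in adj[u]:
            if v not in out:
                out[v] = out[u] + ln
                stack.append(v)
    return out


def _leaf_sides(u, v, adj):
    """Leaves on u's side of edge (u, v)."""
    seen = {u, v}
    stack = [u]
    side = []
    while stack:
        x = stack.pop()
        if x.is_leaf():
            side.append(x)
        for y, _ in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return side


def _mad_best(tree: dendropy.Tree):
    """Best (edge, position-from-tail, score) under the MAD criterion.

    For a candidate root at distance x from node u on edge (u, v), every
    leaf pair (b, c) deviates by ``r = |2 d(b, a) / d(b, c) - 1|`` where a
    is the pair's ancestor under that rooting; pairs spanning the edge have
    ``d(b, a) = d(b, u) + x`` so the mean squared deviation is quadratic in
    x and minimised in closed form. Zero-length pair paths contribute a
    deviation of 0.
    """
    adj = _adjacency(tree)
    leaves = [nd for nd in adj if nd.is_leaf()]
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    dist = {lf: _dist_from(lf, adj) for lf in leaves}

    edges = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            edges.append((node, child, child.edge.length or 0.0))

    n_pairs = len(leaves) * (len(leaves) - 1) // 2
    best = None
    for eidx, (u, v, ln) in enumerate(edges):
        side_u = _leaf_sides(u, v, adj)
        side_v = _leaf_sides(v, u, adj)
        # spanning pairs: r^2 = (alpha*x + beta)^2
        A = B = C = 0.0
        for b in side_u:
            dbu = dist[b][u]
            for c in side_v:
                dbc = dbu + ln + dist[c][v]
                if dbc <= 0:
                    continue  # deviation defined as 0
                alpha = 2.0 / dbc
                beta = 2.0 * dbu / dbc - 1.0
                A += alpha * alpha
                B += 2.0 * alpha * beta
                C += beta * beta
        # same-side pairs: constant deviation
        for side, anchor in ((side_u, u), (side_v, v)):
            for b, c in combinations(side, 2):
                dbc = dist[b][c]
                if dbc <= 0:
                    continue
                da = 0.5 * (dbc + dist[b][anchor] - dist[c][anchor])
                r = 2.0 * da / dbc - 1.0
                C += r * r
        if A > 0:
            x = min(max(-B / (2.0 * A), 0.0), ln)
        else:
            x = 0.0
        score = math.sqrt(max(0.0, (A * x * x + B * x + C)) / n_pairs)
        if best is None or score < best[2] - 1e-15:
            best = (eidx, x, score)
    eidx, x, score = best
    return edges[eidx], x, score


def mad_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree by minimal ancestor deviation.

    Returns a new rooted tree; the winning RMS deviation is attached as
    ``tree.mad_score``. The unrooted topology and the total branch length
    are preserved. A 2-leaf tree is rooted at its midpoint.
    """
    work = tree.clone(depth=1)
    leaves = [lf for lf in work.leaf_node_iter()]
    if len(leaves) == 2:
        total = sum(
            (nd.edge.length or 0.0)
            for nd in work.preorder_node_iter()
            if nd.parent_node is not None
        )
        a, b = leaves
        new = dendropy.Tree(taxon_namespace=work.taxon_namespace)
        root = dendropy.Node()
        for taxon in (a.taxon, b.taxon):
            leaf = dendropy.Node(taxon=taxon)
            root.add_child(leaf)
            leaf.edge.length = total / 2.0
        new.seed_node = root
        new.is_rooted = True
        new.mad_score = 0.0
        return new

    (u, v, ln), x, score = _mad_best(work)
    # split the winning edge with a degree-2 root node (x may be 0 or ln,
    # leaving a zero-length child edge; the root still has degree 2)
    u.remove_child(v)
    mid = dendropy.Node()
    u.add_child(mid)
    mid.edge.length = x
    mid.add_child(v)
    v.edge.length = ln - x
    work.reseed_at(
        mid,
        collapse_unrooted_basal_bifurcation=False,
        suppress_unifurcations=True,
    )
    work.is_rooted = True
    work.mad_score = score
    return work


# ---------------------------------------------------------------------------
# newick io and external delegation


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def run_external_tree(
    msa_path, partition_path=None, options_string: str = "",
    binary: str = "iqtree2", out_prefix=None,
) -> dendropy.Tree:
    """Delegate tree inference to an external ML tool and parse its newick.

    Interface-only hook: forwards ``options_string`` verbatim. Raises a
    RuntimeError naming the built-in builder when the binary is missing.
    """
    if shutil.which(binary) is None:
        raise RuntimeError(
            f"external tree builder {binary!r} not found on PATH; use the "
            "built-in neighbor-joining builder (structcore.phylo.nj_tree) "
            "or install the tool"
        )
    out_prefix = str(out_prefix or msa_path) + ".ext"
    cmd = [binary, "-s", str(msa_path)]
    if partition_path:
        cmd += ["-p", str(partition_path)]
    cmd += ["--prefix", out_prefix]
    cmd += options_string.split()
    result = subprocess.run(cmd, capture_output=True, text=True)
    if result.returncode != 0:
        raise RuntimeError(
            f"{binary} failed ({result.returncode}): {result.stderr[-500:]}"
        )
    treefile = out_prefix + ".treefile"
    try:
        return read_newick(treefile)
    except Exception as exc:  # malformed or missing output
        raise RuntimeError(f"could not parse {binary} output: {exc}") from exc
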