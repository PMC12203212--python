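"""Independent reference implementations used only to check the package.

These deliberately re-derive quantities from first principles (brute-force
enumeration, numeric minimisation) without reusing the package's internal
shortcuts, so agreement is informative.
"""

import math
from itertools import combinations

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar


def random_unrooted_tree(n, rng, min_len=0.05, max_len=1.0, prefix="t"):
    labels = [f"{prefix}{i}" for i in range(n)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lb)) for lb in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(min_len, max_len))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    seed = dendropy.Node()
    for child in nodes:
        seed.add_child(child)
        child.edge.length = float(rng.uniform(min_len, max_len))
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


def _adjacency(tree):
    adj = {}
    for nd in tree.preorder_node_iter():
        adj.setdefault(nd, [])
        for ch in nd.child_nodes():
            ln = ch.edge.length or 0.0
            adj[nd].append((ch, ln))
            adj.setdefault(ch, []).append((nd, ln))
    return adj


def _dist_from(start, adj):
    out = {start: 0.0}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, ln in adj[u]:
            if v not in out:
                out[v] = out[u] + ln
                stack.append(v)
    return out


def grid_mad_score(tree, n_grid=100):
    """Minimum RMS ancestor deviation via a per-edge grid search refined by
    bounded scalar minimisation inside the best grid cell."""
    adj = _adjacency(tree)
    leaves = [n for n in adj if n.is_leaf()]
    dl = {lf: _dist_from(lf, adj) for lf in leaves}
    edges = []
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            edges.append((nd, ch, ch.edge.length or 0.0))
    n_pairs = len(leaves) * (len(leaves) - 1) // 2

    def side(a, b):
        seen = {a, b}
        stack = [a]
        out = []
        while stack:
            x = stack.pop()
            if x.is_leaf():
                out.append(x)
            for y, _ in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return set(out)

    best = np.inf
    for u, v, ln in edges:
        su = side(u, v)

        def f(x):
            s = 0.0
            for b, c in combinations(leaves, 2):
                if (b in su) != (c in su):
                    bb, cc = (b, c) if b in su else (c, b)
                    dbc = dl[bb][u] + ln + dl[cc][v]
                    if dbc <= 0:
                        continue
                    da = dl[bb][u] + x
                else:
                    anchor = u if b in su else v
                    dbc = dl[b][c]
                    if dbc <= 0:
                        continue
                    da = 0.5 * (dbc + dl[b][anchor] - dl[c][anchor])
                r = 2.0 * da / dbc - 1.0
                s += r * r
            return math.sqrt(s / n_pairs)

        xs = np.linspace(0.0, ln, n_grid)
        vals = [f(x) for x in xs]
        k = int(np.argmin(vals))
        cand = vals[k]
        lo, hi = xs[max(0, k - 1)], xs[min(n_grid - 1, k + 1)]
        if hi > lo:
            res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-12})
            cand = min(cand, float(res.fun))
        best = min(best, cand)
    return best


def quartet_topology(tree, four_labels):
    """Induced topology of one 4-leaf subset by direct path inspection:
    returns the label pair grouped together, or None if unresolved."""
    adj = {}
    leaf_of = {}
    for nd in tree.preorder_node_iter():
        adj.setdefault(nd, [])
        for ch in nd.child_nodes():
            adj[nd].append(ch)
            adj.setdefault(ch, []).append(nd)
        if nd.is_leaf():
            leaf_of[nd.taxon.label] = nd

    def path(a, b):
        prev = {a: None}
        stack = [a]
        while stack:
            u = stack.pop()
            if u is b:
                break
            for v in adj[u]:
                if v not in prev:
                    prev[v] = u
                    stack.append(v)
        out = []
        x = b
        while x is not None:
            out.append(x)
            x = prev[x]
        return set(out)

    a, b, c, d = [leaf_of[x] for x in four_labels]
    la, lb, lc, ld = four_labels
    for (p, q, r, s), names in (
        ((a, b, c, d), (la, lb)),
        ((a, c, b, d), (la, lc)),
        ((a, d, b, c), (la, ld)),
    ):
        if not (path(p, q) & path(r, s)):
            return frozenset(names)
    return None
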