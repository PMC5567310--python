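"""Independent oracles used by the tests: brute-force parsimony scoring,
exhaustive topology enumeration, and hand-coded tie-corrected rank statistics.

These deliberately avoid the package's own code paths.
"""

from __future__ import annotations

import itertools

import numpy as np

# Trees are nested structures rooted on taxon 0's pendant edge:
# leaf = int taxon index, internal = [left, right]; full tree = [0, rest].


def enumerate_unrooted(n_taxa: int) -> list:
    """All unrooted binary topologies on taxa 0..n-1 by stepwise edge insertion."""
    assert n_taxa >= 3
    trees = [[0, [1, 2]]]
    for t in range(3, n_taxa):
        nxt = []
        for tree in trees:
            for e in range(_count_edges(tree[1]) + 1):
                nxt.append(_insert(tree, t, e))
        trees = nxt
    return trees


def _count_edges(node) -> int:
    if isinstance(node, int):
        return 0
    return 2 + _count_edges(node[0]) + _count_edges(node[1])


def _insert(tree, taxon, edge_idx):
    """Attach ``taxon`` on edge ``edge_idx``; index 0 is the root edge."""
    import copy

    tree = copy.deepcopy(tree)
    if edge_idx == 0:
        return [0, [tree[1], taxon]]
    counter = [0]

    def walk(node):
        if isinstance(node, int):
            return node
        out = []
        for child in node:
            counter[0] += 1
            if counter[0] == edge_idx:
                out.append([walk_child_untouched(child), taxon])
            else:
                out.append(walk(child))
        return out

    def walk_child_untouched(node):
        return node

    return [tree[0], walk(tree[1])]


def tree_edges(tree):
    """(parent_key, child_key) pairs plus node keys; leaves keyed 'L<i>'."""
    edges = []
    nodes = []

    def walk(node, key):
        nodes.append((key, node))
        if isinstance(node, int):
            return
        for i, child in enumerate(node):
            ck = key + str(i)
            edges.append((key, ck))
            walk(child, ck)

    walk(tree, "r")
    return edges, nodes


def brute_force_parsimony(tree, states: dict[int, int | None]) -> int:
    """Minimum changes of one binary character by exhaustive assignment.

    ``states`` maps taxon index -> 0/1/None ('?'). Free vertices (internal
    nodes and '?' leaves) are enumerated exhaustively.
    """
    edges, nodes = tree_edges(tree)
    fixed = {}
    free = []
    for key, node in nodes:
        if isinstance(node, int):
            s = states.get(node)
            if s is None:
                free.append(key)
            else:
                fixed[key] = s
        else:
            free.append(key)
    best = None
    for combo in itertools.product((0, 1), repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        cost = sum(assign[a] != assign[b] for a, b in edges)
        best = cost if best is None else min(best, cost)
    return best


def tree_to_newick(tree, labels):
    def rec(node):
        if isinstance(node, int):
            return labels[node]
        return "(" + ",".join(rec(c) for c in node) + ")"

    return rec(tree) + ";"


def unrooted_splits(newick: str, labels: list[str]) -> frozenset:
    """Nontrivial bipartitions of an unrooted tree, label-normalised."""
    import dendropy

    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    tree.encode_bipartitions()
    full = frozenset(labels)
    splits = set()
    for b in tree.bipartition_encoding:
        side = frozenset(t.label for t in b.leafset_taxa(tns))
        if 1 < len(side) < len(labels) - 1:
            splits.add(min(side, full - side, key=sorted))
    return frozenset(splits)


# ---------------------------------------------------------------------------
# rank statistics, tie-corrected, straight from the textbook formulas


def kruskal_wallis_h(groups: list[np.ndarray]) -> float:
    data = np.concatenate(groups)
    n = len(data)
    order = np.argsort(data, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = data[order]
    i = 0
    pos = np.arange(1, n + 1, dtype=float)
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = pos[i:j].mean()
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(data, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    correction = 1.0 - tie_term / (n**3 - n)
    return h / correction


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of sample x (ties get half credit)."""
    both = np.concatenate([x, y])
    n = len(both)
    order = np.argsort(both, kind="mergesort")
    ranks = np.empty(n)
    sv = both[order]
    i = 0
    pos = np.arange(1, n + 1, dtype=float)
    while i < n:
        j = i
        while j < n and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = pos[i:j].mean()
        i = j
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)
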