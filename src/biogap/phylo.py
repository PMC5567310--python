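"""Supertree construction and phylodiversity metrics.

Source phylogenies (unit branch lengths throughout — published trees rarely
share comparable branch lengths, so every branch counts 1) are merged by
matrix representation with parsimony (MRP): each non-root clade of each
source tree becomes one binary character (members 1, other taxa of that tree
0, taxa absent from the tree '?'), and the supertree is the most
parsimonious tree for the concatenated matrix, found by a parsimony-ratchet
heuristic (alternating hill-climbing under reweighted and original
characters to escape local optima).

Downstream metrics: Faith's phylogenetic diversity (rooted variant — the
length of the minimal root-spanning subtree of a species set) and
phylogenetic weighted endemism (each branch contributes its length divided
by the number of grid cells its descendant clade occupies).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

MISSING = -1  # '?' state in MRP matrices

# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree; raises ValueError with position info if malformed."""
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def unit_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Set every branch length to 1 (in place; returns the tree)."""
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = 1.0
    return tree


def prune_to_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on the retained tips; degree-2 nodes suppressed."""
    keep = set(taxa)
    present = keep & set(tip_labels(tree))
    if not present:
        raise ValueError("no requested taxa present in the tree")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(present))
    pruned.suppress_unifurcations()
    return pruned


# ---------------------------------------------------------------------------
# Matrix representation with parsimony


@dataclass
class MRPMatrix:
    """Binary character matrix over {0, 1, ?} encoding source-tree clades."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_chars) int8; MISSING for '?'
    provenance: list[tuple[int, int]] = field(default_factory=list)  # (tree, node) per char

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return self.matrix.shape[1]

    def column_text(self, taxon_idx: int) -> str:
        return "".join(
            "?" if v == MISSING else str(int(v)) for v in self.matrix[taxon_idx]
        )

    def as_phylip(self) -> str:
        width = max(len(t) for t in self.taxa) + 2
        lines = [f"{self.n_taxa} {self.n_chars}"]
        for i, t in enumerate(self.taxa):
            lines.append(f"{t.ljust(width)}{self.column_text(i)}")
        return "\n".join(lines) + "\n"

    def as_nexus(self) -> str:
        rows = "\n".join(
            f"    {t} {self.column_text(i)}" for i, t in enumerate(self.taxa)
        )
        return (
            "#NEXUS\nBEGIN DATA;\n"
            f"  DIMENSIONS NTAX={self.n_taxa} NCHAR={self.n_chars};\n"
            "  FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS=\"01\";\n"
            f"  MATRIX\n{rows}\n  ;\nEND;\n"
        )


def mrp_encode(source_trees: Sequence[dendropy.Tree]) -> MRPMatrix:
    """Baum-Ragan coding: one character per non-root internal node."""
    if not source_trees:
        raise ValueError("need at least one source tree")
    all_taxa = sorted({t for tr in source_trees for t in tip_labels(tr)})
    index = {t: i for i, t in enumerate(all_taxa)}
    columns: list[np.ndarray] = []
    provenance: list[tuple[int, int]] = []
    for ti, tree in enumerate(source_trees):
        tree_taxa = tip_labels(tree)
        if len(tree_taxa) < 3:
            raise ValueError(f"source tree {ti} has fewer than 3 tips")
        tree_rows = [index[t] for t in tree_taxa]
        for ni, node in enumerate(tree.preorder_internal_node_iter()):
            if node.parent_node is None:
                continue  # root clade = all taxa, no informative 0s
            members = {leaf.taxon.label for leaf in node.leaf_iter()}
            if len(members) >= len(tree_taxa):
                continue
            col = np.full(len(all_taxa), MISSING, dtype=np.int8)
            col[tree_rows] = 0
            col[[index[m] for m in members]] = 1
            columns.append(col)
            provenance.append((ti, ni))
    matrix = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(all_taxa), 0), dtype=np.int8)
    )
    return MRPMatrix(taxa=all_taxa, matrix=matrix, provenance=provenance)


# ---------------------------------------------------------------------------
# Parsimony scoring (Hartigan minimum-mutation count; exact on any arity)


def _state_masks(matrix: np.ndarray) -> np.ndarray:
    """Per-taxon bitmasks: state 0 -> 0b01, 1 -> 0b10, '?' -> 0b11."""
    masks = np.empty(matrix.shape, dtype=np.int8)
    masks[matrix == 0] = 1
    masks[matrix == 1] = 2
    masks[matrix == MISSING] = 3
    return masks


def _hartigan_combine(child_masks: list[np.ndarray], weights: np.ndarray):
    count0 = np.zeros(child_masks[0].shape, dtype=np.int32)
    count1 = np.zeros_like(count0)
    for m in child_masks:
        count0 += (m & 1) != 0
        count1 += (m & 2) != 0
    k = np.maximum(count0, count1)
    cost = float(np.sum(weights * (len(child_masks) - k)))
    mask = ((count0 == k) * 1 | (count1 == k) * 2).astype(np.int8)
    return mask, cost


def fitch_score(
    tree: dendropy.Tree, mrp: MRPMatrix, weights: np.ndarray | None = None
) -> float:
    """Minimum number of state changes of the matrix on the tree.

    '?' is full ambiguity; tips of the tree absent from the matrix are
    treated as all-'?'. Multifurcations are scored exactly.
    """
    if weights is None:
        weights = np.ones(mrp.n_chars)
    masks = _state_masks(mrp.matrix)
    row = {t: i for i, t in enumerate(mrp.taxa)}
    total = 0.0
    state: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = row.get(node.taxon.label)
            state[id(node)] = (
                masks[i] if i is not None else np.full(mrp.n_chars, 3, np.int8)
            )
        else:
            kids = [state.pop(id(c)) for c in node.child_nodes()]
            if len(kids) == 1:
                state[id(node)] = kids[0]
                continue
            state[id(node)], cost = _hartigan_combine(kids, weights)
            total += cost
    return total


# ---------------------------------------------------------------------------
# Search trees: rooted-at-taxon-0 binary nested lists (leaf = taxon index)


def _fold_binary(children: list):
    node = children[0]
    for c in children[1:]:
        node = [node, c]
    return node


def _dendropy_to_search(tree: dendropy.Tree, taxa: Sequence[str]):
    """Convert to the internal search form: [leaf0, rest], binary, unrooted
    semantics anchored on taxon 0's pendant edge."""
    index = {t: i for i, t in enumerate(taxa)}
    adj: dict[int, list] = {}
    leaf_of: dict[int, int] = {}
    nodes = list(tree.preorder_node_iter())
    for node in nodes:
        adj.setdefault(id(node), [])
        if node.is_leaf():
            leaf_of[id(node)] = index[node.taxon.label]
        for child in node.child_nodes():
            adj[id(node)].append(child)
            adj.setdefault(id(child), []).append(node)
    node_by_id = {id(n): n for n in nodes}
    start = next(n for n in nodes if n.is_leaf() and index[n.taxon.label] == 0)

    def build(nid: int, parent_id: int):
        if nid in leaf_of and leaf_of[nid] != 0:
            return leaf_of[nid]
        kids = [id(k) for k in adj[nid] if id(k) != parent_id]
        built = [build(k, nid) for k in kids]
        if len(built) == 1:
            return built[0]
        return _fold_binary(built)

    anchor = adj[id(start)][0]
    return [0, build(id(anchor), id(start))]


def _search_to_newick(node, taxa: Sequence[str]) -> str:
    if isinstance(node, int):
        return taxa[node]
    return "(" + ",".join(_search_to_newick(c, taxa) for c in node) + ")"


def _search_to_tree(node, taxa: Sequence[str]) -> dendropy.Tree:
    tree = read_newick(_search_to_newick(node, taxa) + ";")
    return unit_branch_lengths(tree)


def _score_search(node, masks: np.ndarray, weights: np.ndarray) -> float:
    def rec(n):
        if isinstance(n, int):
            return masks[n], 0.0
        (lm, lc), (rm, rc) = rec(n[0]), rec(n[1])
        inter = lm & rm
        miss = inter == 0
        cost = lc + rc + float(weights[miss].sum())
        return np.where(miss, lm | rm, inter).astype(np.int8), cost

    return rec(node)[1]


def _nni_neighbors(tree):
    """All trees one nearest-neighbour interchange away (unrooted moves).

    Internal edges are those whose parent endpoint is an internal node other
    than the anchoring root (the root subdivides taxon 0's pendant edge).
    """
    out = []
    edges = []

    def walk(node, parent):
        if isinstance(node, int):
            return
        if parent is not None and parent is not tree:
            edges.append((parent, node))
        for child in node:
            walk(child, node)

    walk(tree, None)
    for parent, node in edges:
        sib_idx = 0 if parent[1] is node else 1
        for ci in (0, 1):
            t2 = copy.deepcopy(tree)
            p2, n2 = _find(t2, tree, parent, node)
            p2[sib_idx], n2[ci] = n2[ci], p2[sib_idx]
            out.append(t2)
    return out


def _find(copy_root, orig_root, parent, node):
    """Locate the copies of (parent, node) in the deep-copied tree by path."""
    path = []

    def locate(cur, target, trail):
        if cur is target:
            path.extend(trail)
            return True
        if isinstance(cur, int):
            return False
        return locate(cur[0], target, trail + [0]) or locate(
            cur[1], target, trail + [1]
        )

    locate(orig_root, node, [])
    cur = copy_root
    par = None
    for step in path:
        par = cur
        cur = cur[step]
    return par, cur


def _hill_climb(tree, masks, weights):
    best, best_score = tree, _score_search(tree, masks, weights)
    improved = True
    while improved:
        improved = False
        for nb in _nni_neighbors(best):
            s = _score_search(nb, masks, weights)
            if s < best_score - 1e-12:
                best, best_score, improved = nb, s, True
                break
    return best, best_score


def _nj_start(mrp: MRPMatrix):
    """Neighbour-joining on MRP Hamming distances as the starting tree."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    m = mrp.matrix
    n = mrp.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (m[i] != MISSING) & (m[j] != MISSING)
            d[i, j] = d[j, i] = (
                float(np.mean(m[i, both] != m[j, both])) if both.any() else 0.5
            )
    d = d + 1e-9 * (1 - np.eye(n))  # NJ dislikes exact-zero off-diagonals
    tree = nj(DistanceMatrix(d, ids=[str(i) for i in range(n)]))
    dtree = read_newick(str(tree))
    # relabel numeric ids back to taxa so the converter can anchor on taxon 0
    for leaf in dtree.leaf_node_iter():
        leaf.taxon.label = mrp.taxa[int(leaf.taxon.label)]
    return _dendropy_to_search(dtree, mrp.taxa)


@dataclass
class SupertreeResult:
    tree: dendropy.Tree
    score: float
    log: list[tuple[int, float]]


def ratchet_search(
    mrp: MRPMatrix,
    iterations: int = 200,
    seed: int = 0,
    upweight_fraction: float = 0.25,
    weight_factor: float = 2.0,
    start_tree: dendropy.Tree | None = None,
) -> SupertreeResult:
    """Parsimony-ratchet search for the MRP supertree.

    Alternates NNI hill-climbing under perturbed character weights (a random
    quarter of characters doubled) with hill-climbing under the original
    weights; the incumbent is never replaced by a worse tree. Deterministic
    under a fixed seed.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if mrp.n_taxa < 4:
        raise ValueError("ratchet search needs at least 4 taxa")
    if mrp.n_chars == 0:
        raise ValueError("empty character matrix")
    rng = np.random.default_rng(seed)
    masks = _state_masks(mrp.matrix)
    w0 = np.ones(mrp.n_chars)

    current = (
        _dendropy_to_search(start_tree, mrp.taxa)
        if start_tree is not None
        else _nj_start(mrp)
    )
    current, cur_score = _hill_climb(current, masks, w0)
    best, best_score = current, cur_score
    log = [(0, best_score)]
    n_up = max(1, int(round(upweight_fraction * mrp.n_chars)))
    for it in range(1, iterations + 1):
        w = w0.copy()
        w[rng.choice(mrp.n_chars, size=n_up, replace=False)] *= weight_factor
        perturbed, _ = _hill_climb(current, masks, w)
        candidate, cand_score = _hill_climb(perturbed, masks, w0)
        if cand_score <= cur_score + 1e-12:
            current, cur_score = candidate, cand_score
        if cand_score < best_score - 1e-12:
            best, best_score = candidate, cand_score
        log.append((it, best_score))
    return SupertreeResult(
        tree=_search_to_tree(best, mrp.taxa), score=best_score, log=log
    )


# ---------------------------------------------------------------------------
# Phylodiversity metrics


def faith_pd(tree: dendropy.Tree, species_set: Iterable[str]) -> float:
    """Rooted Faith PD: total branch length of the minimal subtree that
    connects the species set to the root (shared branches counted once)."""
    wanted = set(species_set)
    if not wanted:
        return 0.0
    tips = set(tip_labels(tree))
    missing = wanted - tips
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)[:5]}")
    seen: set[int] = set()
    total = 0.0
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in wanted:
            continue
        node = leaf
        while node is not None and id(node) not in seen:
            seen.add(id(node))
            if node.parent_node is not None:
                total += node.edge.length if node.edge.length is not None else 1.0
            node = node.parent_node
    return total


@dataclass
class BranchRanges:
    """Per-branch length and occupied-cell set (union over descendant tips)."""

    lengths: np.ndarray
    ranges: list[frozenset[int]]
    labels: list[str]  # tip label or clade description

    @property
    def total_recorded_length(self) -> float:
        return float(
            sum(l for l, r in zip(self.lengths, self.ranges) if r)
        )


def branch_ranges(
    tree: dendropy.Tree, species_ranges: Mapping[str, frozenset[int]]
) -> BranchRanges:
    lengths, ranges, labels = [], [], []
    acc: dict[int, set[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            cells = set(species_ranges.get(node.taxon.label, ()))
            label = node.taxon.label
        else:
            cells = set()
            for child in node.child_nodes():
                cells |= acc.pop(id(child))
            label = "clade:" + ",".join(
                sorted(l.taxon.label for l in node.leaf_iter())[:4]
            )
        acc[id(node)] = cells
        if node.parent_node is None:
            continue
        lengths.append(node.edge.length if node.edge.length is not None else 1.0)
        ranges.append(frozenset(cells))
        labels.append(label)
    return BranchRanges(np.array(lengths), ranges, labels)


def pwe(
    tree: dendropy.Tree,
    species_ranges: Mapping[str, frozenset[int]],
    cell_ids: Iterable[int] | None = None,
) -> pd.Series:
    """Per-cell phylogenetic weighted endemism.

    Each branch spreads its length evenly across the cells its descendant
    clade occupies; a cell's PWE is the sum of those shares.
    """
    br = branch_ranges(tree, species_ranges)
    cells = set(int(c) for c in cell_ids) if cell_ids is not None else set()
    for r in br.ranges:
        cells |= r
    out = pd.Series(0.0, index=pd.Index(sorted(cells), name="cell_id"))
    for length, rng in zip(br.lengths, br.ranges):
        if rng:
            out[list(rng)] += length / len(rng)
    return out


@dataclass
class LineageProtection:
    length_proportion: float
    count_proportion: float
    total_length: float
    n_branches: int


def lineage_protection(
    tree: dendropy.Tree,
    species_ranges: Mapping[str, frozenset[int]],
    pa_cells: Iterable[int],
) -> LineageProtection:
    """Share of lineage (branch) length whose range touches a protected cell.

    Only branches with a recorded range enter the denominator. The headline
    figure weights lineages by branch length; the branch-count share is
    reported alongside.
    """
    pa = set(int(c) for c in pa_cells)
    br = branch_ranges(tree, species_ranges)
    tot_len = prot_len = 0.0
    n = n_prot = 0
    for length, rng in zip(br.lengths, br.ranges):
        if not rng:
            continue
        tot_len += length
        n += 1
        if rng & pa:
            prot_len += length
            n_prot += 1
    if n == 0:
        return LineageProtection(0.0, 0.0, 0.0, 0)
    return LineageProtection(prot_len / tot_len, n_prot / n, tot_len, n)
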