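"""Species-tree inference: chunked parsimony, consensus, averaged lengths.

Isoform assignments that still contain every requested species are codon
aligned, concatenated and cut into equal-length chunks (a jackknife over
genomic position).  Each chunk is column-filtered and a parsimony tree is
built for it: Fitch score on codon states, hill-climbing NNI search from a
neighbour-joining start (exhaustive search for ≤ 6 taxa).  Branch lengths
are expected changes per branch under a uniform sample of most-parsimonious
reconstructions, divided by the site count and corrected for unseen
multiple hits with the many-state Poisson inversion −log(1−c).  The chunk
trees are summarised by a strict-majority consensus whose branch lengths
are the arithmetic mean over the chunk trees containing each split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .column_filter import FilterParams, filter_columns
from .seq_io import CodonAlignment
from .trees import Node, SpeciesTree, split_key

__all__ = ["ChunkTree", "build_superalignment", "parsimony_tree",
           "consensus_with_lengths", "infer_species_tree"]

_FULL_MASK = np.uint64((1 << 61) - 1)


@dataclass
class ChunkTree:
    tree: SpeciesTree
    score: int
    chunk_index: int = 0
    n_sites: int = 0


# ---------------------------------------------------------------------------
# superalignment


def build_superalignment(aligned_assignments: list[CodonAlignment],
                         species: Optional[set] = None,
                         n_chunks: int = 20,
                         filter_params: Optional[FilterParams] = None):
    """Concatenate codon alignments covering all `species`, cut into chunks,
    and column-filter each chunk.

    Returns (superalignment, filtered chunk alignments).  Alignments missing
    a requested species are ignored; if none qualifies a ValueError asks the
    user to provide a tree instead.
    """
    if species is None and aligned_assignments:
        species = set(aligned_assignments[0].species)
    complete = [a for a in aligned_assignments
                if set(a.species) == set(species)]
    if not complete:
        raise ValueError(
            "no assignment contains all requested species after filtering; "
            "provide a species tree explicitly")
    order = sorted(species)
    rows = {sp: [] for sp in order}
    for a in complete:
        for sp in order:
            rows[sp].append(a.row(sp))
    superalignment = CodonAlignment(order, ["".join(rows[sp]) for sp in order])
    n_cols = superalignment.n_codons
    n_chunks = max(1, min(n_chunks, n_cols))
    size = int(np.ceil(n_cols / n_chunks))
    chunks = []
    for start in range(0, n_cols, size):
        keep = np.zeros(n_cols, dtype=bool)
        keep[start:start + size] = True
        chunk = superalignment.subset_columns(keep)
        mask = filter_columns(chunk, filter_params)
        filtered = chunk.subset_columns(mask.keep)
        if filtered.n_codons:
            chunks.append(filtered)
    return superalignment, chunks


# ---------------------------------------------------------------------------
# unrooted topology as adjacency (internal representation of the search)


class _Topology:
    """Unrooted binary topology over leaves 0..n-1 (internal degree 3)."""

    def __init__(self, n_leaves: int):
        self.n = n_leaves
        self.adj: dict[int, list[int]] = {}
        self.next_id = n_leaves

    def add_edge(self, u, v):
        self.adj.setdefault(u, []).append(v)
        self.adj.setdefault(v, []).append(u)

    def remove_edge(self, u, v):
        self.adj[u].remove(v)
        self.adj[v].remove(u)

    def copy(self) -> "_Topology":
        t = _Topology(self.n)
        t.adj = {k: list(v) for k, v in self.adj.items()}
        t.next_id = self.next_id
        return t

    def internal_edges(self):
        return [(u, v) for u in self.adj for v in self.adj[u]
                if u < v and u >= self.n and v >= self.n]

    def rooted_children(self, root_leaf: int = 0):
        """Orient away from `root_leaf`: postorder list of (node, children)."""
        start = self.adj[root_leaf][0]
        order = []
        stack = [(start, root_leaf)]
        visiting = []
        while stack:
            node, parent = stack.pop()
            kids = [x for x in self.adj[node] if x != parent]
            visiting.append((node, parent, kids))
            for k in kids:
                stack.append((k, node))
        # children lists already known; produce postorder
        seen = {}
        for node, parent, kids in reversed(visiting):
            order.append((node, kids))
        return order  # postorder (children appear before parents)

    def splits(self) -> dict[int, frozenset]:
        """node → leafset on its side away from leaf 0 (rooted orientation)."""
        below: dict[int, frozenset] = {}
        for node, kids in self.rooted_children(0):
            if node < self.n:
                below[node] = frozenset([node])
            else:
                below[node] = frozenset().union(*[below[k] for k in kids])
        return below


def _nj_topology(chunk_states: np.ndarray, names: list[str]) -> _Topology:
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = chunk_states[i], chunk_states[j]
            ok = (a >= 0) & (b >= 0)
            p = float((a[ok] != b[ok]).mean()) if ok.any() else 0.0
            D[i, j] = D[j, i] = -np.log(max(1.0 - p, 1e-6))
    tree = nj(DistanceMatrix(D, [str(i) for i in range(n)]))
    topo = _Topology(n)
    counter = [n]

    def conv(node) -> int:
        if node.is_tip():
            return int(node.name)
        nid = counter[0]
        counter[0] += 1
        topo.next_id = counter[0]
        kids = [conv(c) for c in node.children]
        for k in kids:
            topo.add_edge(nid, k)
        return nid

    root_kids = [conv(c) for c in tree.children]
    if len(root_kids) == 2:
        # binary root: splice out
        a, b = root_kids
        topo.add_edge(a, b)
    else:
        nid = counter[0]
        counter[0] += 1
        topo.next_id = counter[0]
        for k in root_kids:
            topo.add_edge(nid, k)
    _binarize(topo)
    return topo


def _binarize(topo: _Topology):
    """Resolve any multifurcation deterministically (arbitrary caterpillar)."""
    changed = True
    while changed:
        changed = False
        for node in list(topo.adj):
            if node < topo.n:
                continue
            while len(topo.adj[node]) > 3:
                a, b = sorted(topo.adj[node])[:2]
                new = topo.next_id
                topo.next_id += 1
                topo.remove_edge(node, a)
                topo.remove_edge(node, b)
                topo.add_edge(new, a)
                topo.add_edge(new, b)
                topo.add_edge(new, node)
                changed = True


def _leaf_masks(states: np.ndarray) -> np.ndarray:
    """(n_seq, n_pat) uint64 Fitch state sets (missing → full set)."""
    masks = np.where(states >= 0,
                     np.left_shift(np.uint64(1),
                                   states.clip(0).astype(np.uint64)),
                     _FULL_MASK)
    return masks.astype(np.uint64)


def _fitch_score(topo: _Topology, masks: np.ndarray,
                 counts: np.ndarray) -> int:
    node_mask: dict[int, np.ndarray] = {}
    changes = np.zeros(masks.shape[1], dtype=np.int32)
    for node, kids in topo.rooted_children(0):
        if node < topo.n:
            node_mask[node] = masks[node]
            continue
        m1, m2 = node_mask.pop(kids[0]), node_mask.pop(kids[1])
        inter = m1 & m2
        empty = inter == 0
        node_mask[node] = np.where(empty, m1 | m2, inter)
        changes += empty
    top = topo.adj[0][0]
    inter = node_mask[top] & masks[0]
    changes += (inter == 0)
    return int((changes * counts).sum())


def _all_topologies(n: int):
    """Every unrooted binary topology (used exhaustively for ≤ 6 taxa)."""
    base = _Topology(n)
    c = base.next_id
    base.next_id += 1
    for leaf in (0, 1, 2):
        base.add_edge(c, leaf)
    trees = [base]
    for leaf in range(3, n):
        new_trees = []
        for t in trees:
            edges = [(u, v) for u in t.adj for v in t.adj[u] if u < v]
            for (u, v) in edges:
                t2 = t.copy()
                mid = t2.next_id
                t2.next_id += 1
                t2.remove_edge(u, v)
                t2.add_edge(u, mid)
                t2.add_edge(mid, v)
                t2.add_edge(mid, leaf)
                new_trees.append(t2)
        trees = new_trees
    return trees


def _nni_neighbours(topo: _Topology, edge):
    u, v = edge
    a, b = [x for x in topo.adj[u] if x != v][:2]
    c, d = [x for x in topo.adj[v] if x != u][:2]
    for swap_u, swap_v in ((b, c), (b, d)):
        t2 = topo.copy()
        t2.remove_edge(u, swap_u)
        t2.remove_edge(v, swap_v)
        t2.add_edge(u, swap_v)
        t2.add_edge(v, swap_u)
        yield t2


# ---------------------------------------------------------------------------
# branch lengths by uniform MP reconstruction sampling


def _sankoff_lengths(topo: _Topology, states: np.ndarray, counts: np.ndarray,
                     n_sites: int, rng: np.random.Generator,
                     n_samples: int = 3) -> dict[frozenset, float]:
    """Expected changes per branch / site, with multiple-hit correction.

    Unit-cost Sankoff DP with solution counting, then top-down sampling
    uniform over most-parsimonious reconstructions.
    """
    n_pat = states.shape[1]
    INF = np.int32(1 << 20)
    post = topo.rooted_children(0)
    cost: dict[int, np.ndarray] = {}
    for node, kids in post:
        if node < topo.n:
            c = np.full((n_pat, 61), INF, dtype=np.int32)
            s = states[node]
            obs = s >= 0
            c[obs, s[obs]] = 0
            c[~obs, :] = 0
            cost[node] = c
        else:
            total = np.zeros((n_pat, 61), dtype=np.int32)
            for k in kids:
                ck = cost[k]
                m = ck.min(axis=1, keepdims=True)
                total += np.minimum(ck, m + 1)
            cost[node] = total

    children = {node: kids for node, kids in post}
    top = topo.adj[0][0]
    # treat leaf 0 as the root's parent: the edge (0, top) is scored too
    edge_changes = {  # child node → sampled change counts
        node: 0.0 for node, _ in post}
    leaf0_changes = 0.0

    below = topo.splits()
    for _ in range(n_samples):
        state_of: dict[int, np.ndarray] = {}
        # root choice: minimise cost(top) + [state != leaf0 state]
        s0 = states[0]
        c_top = cost[top]
        stay = c_top.copy()
        rows = np.arange(n_pat)
        obs = s0 >= 0
        add = np.ones((n_pat, 61), dtype=np.int32)
        add[~obs] = 0
        add[obs, s0[obs]] = 0
        tot = c_top + add
        m = tot.min(axis=1, keepdims=True)
        choice = _sample_argmin(tot, m, rng)
        state_of[top] = choice
        chg = np.ones(n_pat)
        chg[~obs] = 0.0
        chg[obs & (choice == s0)] = 0.0
        leaf0_changes += float((chg * counts).sum())
        stack = [top]
        while stack:
            node = stack.pop()
            for k in children.get(node, []):
                ck = cost[k]
                parent_state = state_of[node]
                m = ck.min(axis=1, keepdims=True)
                contrib = np.minimum(ck, m + 1)
                add = np.ones((n_pat, 61), dtype=np.int32)
                add[rows, parent_state] = 0
                tot = ck + add
                mm = tot.min(axis=1, keepdims=True)
                choice = _sample_argmin(tot, mm, rng)
                state_of[k] = choice
                chg = (choice != parent_state).astype(float)
                edge_changes[k] += float((chg * counts).sum())
                if k >= topo.n:
                    stack.append(k)

    out: dict[frozenset, float] = {}
    denom = max(n_sites, 1) * n_samples
    for node, _ in post:
        c = edge_changes[node] / denom
        out[below[node]] = float(-np.log(max(1.0 - c, 1e-3))) + 0.0
    c0 = leaf0_changes / denom
    out[frozenset([0])] = float(-np.log(max(1.0 - c0, 1e-3))) + 0.0
    return out


def _sample_argmin(tot: np.ndarray, m: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Per row, sample uniformly among columns achieving the minimum."""
    is_min = tot == m
    weights = is_min.astype(float)
    weights /= weights.sum(axis=1, keepdims=True)
    u = rng.random((tot.shape[0], 1))
    return (weights.cumsum(axis=1) > u).argmax(axis=1)


# ---------------------------------------------------------------------------
# public operations


def parsimony_tree(chunk: CodonAlignment, chunk_index: int = 0,
                   seed: int = 0) -> ChunkTree:
    """Most-parsimonious unrooted tree of one chunk (NNI from an NJ start;
    exhaustive for ≤ 6 taxa), with sampled-reconstruction branch lengths."""
    if chunk.n_seqs < 3:
        raise ValueError("need at least 3 sequences")
    if chunk.n_codons < 1:
        raise ValueError("empty chunk")
    names = list(chunk.species)
    states_full = chunk.to_state_matrix()
    patterns, counts = np.unique(states_full, axis=1, return_counts=True)
    masks = _leaf_masks(patterns)
    counts = counts.astype(np.int64)

    if chunk.n_seqs <= 6:
        candidates = _all_topologies(chunk.n_seqs)
        scored = [(_fitch_score(t, masks, counts), i, t)
                  for i, t in enumerate(candidates)]
        score, _, topo = min(scored, key=lambda x: (x[0], x[1]))
    else:
        topo = _nj_topology(patterns, names)
        score = _fitch_score(topo, masks, counts)
        improved = True
        while improved:
            improved = False
            for edge in topo.internal_edges():
                for cand in _nni_neighbours(topo, edge):
                    s = _fitch_score(cand, masks, counts)
                    if s < score:
                        topo, score = cand, s
                        improved = True
                        break
                if improved:
                    break

    rng = np.random.default_rng(seed + 7919 * chunk_index)
    lengths = _sankoff_lengths(topo, patterns, counts, chunk.n_codons, rng)
    tree = _topology_to_tree(topo, names, lengths)
    return ChunkTree(tree, score, chunk_index, chunk.n_codons)


def _topology_to_tree(topo: _Topology, names: list[str],
                      lengths: dict[frozenset, float]) -> SpeciesTree:
    below = topo.splits()

    def build(node) -> Node:
        if node < topo.n:
            return Node(names[node], lengths.get(frozenset([node]), 0.0))
        kids = [k for k in topo.adj[node]
                if below.get(k, frozenset()) < below[node]]
        return Node(None, lengths.get(below[node], 0.0),
                    [build(k) for k in kids])

    top = topo.adj[0][0]
    root = Node(None, 0.0, [Node(names[0], lengths.get(frozenset([0]), 0.0))]
                + [build(k) for k in topo.adj[top] if k != 0])
    return SpeciesTree(root)


def consensus_with_lengths(chunk_trees: list[ChunkTree]):
    """Strict-majority consensus with averaged branch lengths.

    Internal branch lengths average over the chunk trees containing the
    split; terminal branches average over all chunk trees.  Returns
    (SpeciesTree, support dict: canonical split → frequency).
    """
    if len(chunk_trees) < 2:
        raise ValueError("need at least 2 chunk trees")
    trees = [c.tree for c in chunk_trees]
    leaves = trees[0].leaves
    if any(t.leaves != leaves for t in trees):
        raise ValueError("chunk trees must share one leaf set")
    n = len(trees)
    split_count: dict[frozenset, int] = {}
    split_lengths: dict[frozenset, list[float]] = {}
    term_lengths: dict[str, list[float]] = {sp: [] for sp in leaves}
    for t in trees:
        for ls, node in t.branches().items():
            if len(ls) == 1:
                term_lengths[next(iter(ls))].append(node.length)
            elif len(ls) < len(leaves) - 1:
                key = split_key(ls, leaves)
                split_count[key] = split_count.get(key, 0) + 1
                split_lengths.setdefault(key, []).append(node.length)
            else:  # complement of a terminal: fold into that terminal branch
                sp = next(iter(leaves - ls))
                term_lengths[sp].append(node.length)
    majority = {s for s, c in split_count.items() if c / n > 0.5}
    support = {s: split_count[s] / n for s in majority}

    ref = min(leaves)
    oriented = [s if ref not in s else leaves - s for s in majority]
    oriented.sort(key=len)
    root = Node(None, 0.0, [])
    node_of: dict[frozenset, Node] = {}
    # nest splits smallest-first under their smallest superset
    placed: list[tuple[frozenset, Node]] = []
    for s in oriented:
        node = Node(None, float(np.mean(split_lengths[split_key(s, leaves)])))
        node_of[s] = node
        placed.append((s, node))
    leaf_nodes = {sp: Node(sp, float(np.mean(term_lengths[sp])))
                  for sp in leaves}
    for sp in sorted(leaves):
        host = None
        for s, node in placed:
            if sp in s:
                host = node
                break
        (host or root).children.append(leaf_nodes[sp])
    for s, node in placed:
        host = None
        for s2, node2 in placed:
            if s < s2:
                host = node2
                break
        (host or root).children.append(node)
    tree = SpeciesTree(root)
    return tree, support


def infer_species_tree(aligned_assignments: list[CodonAlignment],
                       species: Optional[set] = None, n_chunks: int = 20,
                       filter_params: Optional[FilterParams] = None,
                       seed: int = 0, refine_lengths: bool = True):
    """Full tree step: superalignment → chunk parsimony → consensus.

    With `refine_lengths` the consensus branch lengths (corrected parsimony
    change fractions) are replaced by maximum-likelihood estimates under the
    single-ω codon model on a thinned superalignment — parsimony counts
    systematically undershoot on long branches.
    """
    super_aln, chunks = build_superalignment(aligned_assignments, species,
                                             n_chunks, filter_params)
    chunk_trees = [parsimony_tree(chunk, i, seed=seed)
                   for i, chunk in enumerate(chunks)]
    if len(chunk_trees) == 1:
        tree, support = chunk_trees[0].tree, {}
    else:
        tree, support = consensus_with_lengths(chunk_trees)
    if refine_lengths:
        from .codon_model import estimate_branch_lengths
        mask = filter_columns(super_aln, filter_params)
        filtered = super_aln.subset_columns(mask.keep)
        tree = estimate_branch_lengths(filtered, tree)
    return tree, support
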