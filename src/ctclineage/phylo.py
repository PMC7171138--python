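"""Maximum-parsimony phylogeny of tumor samples from binary alteration data.

Non-silent somatic alterations present in at least two samples are encoded
as binary characters over samples (present = VAF > 0).  Unrooted binary
trees are scored with the Fitch parsimony criterion and searched with the
parsimony ratchet: alternating rounds of NNI hill-climbing under randomly
upweighted characters and under the original weights, which lets the search
escape local optima.  For branch assignment the tree is rooted at an
all-zero germline outgroup and each alteration is mapped to the edge whose
downstream leaf set equals its presence set; alterations fitting no edge are
flagged homoplastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

Adjacency = dict[int, list[int]]


# ---------------------------------------------------------------------------
# Tree plumbing (unrooted binary trees; leaves are 0..n-1, internals >= n)


def _copy(adj: Adjacency) -> Adjacency:
    return {k: list(v) for k, v in adj.items()}


def _edges(adj: Adjacency) -> list[tuple[int, int]]:
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _star3(n_leaves: int) -> Adjacency:
    c = n_leaves
    adj: Adjacency = {c: [0, 1, 2]}
    for i in range(3):
        adj[i] = [c]
    return adj


def _attach_leaf(adj: Adjacency, leaf: int, edge: tuple[int, int],
                 new_internal: int) -> Adjacency:
    u, v = edge
    out = _copy(adj)
    out[u].remove(v)
    out[v].remove(u)
    out[u].append(new_internal)
    out[v].append(new_internal)
    out[new_internal] = [u, v, leaf]
    out[leaf] = [new_internal]
    return out


def enumerate_topologies(n_leaves: int) -> Iterator[Adjacency]:
    """All unrooted binary topologies over ``n_leaves`` labelled leaves.

    Yields (2n-5)!! trees by sequential leaf addition; feasible up to ~8
    leaves, used as an exhaustive oracle.
    """
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves for an unrooted topology")

    def grow(adj: Adjacency, next_leaf: int, next_internal: int):
        if next_leaf == n_leaves:
            yield adj
            return
        for edge in _edges(adj):
            yield from grow(_attach_leaf(adj, next_leaf, edge, next_internal),
                            next_leaf + 1, next_internal + 1)

    yield from grow(_star3(n_leaves), 3, n_leaves + 1)


def _rooted_orders(adj: Adjacency, root_leaf: int = 0
                   ) -> tuple[list[int], dict[int, list[int]]]:
    """Postorder node list and child map when hanging the tree from a leaf."""
    children: dict[int, list[int]] = {}
    post: list[int] = []
    stack = [(root_leaf, adj[root_leaf][0])]
    visit = []
    seen = {root_leaf}
    while stack:
        parent, node = stack.pop()
        seen.add(node)
        kids = [x for x in adj[node] if x != parent]
        children[node] = kids
        visit.append(node)
        for k in kids:
            stack.append((node, k))
    post = list(reversed(visit))
    return post, children


def fitch_score(
    adj: Adjacency,
    chars: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted Fitch parsimony score of binary characters on a topology.

    ``chars`` is a (n_leaves, n_chars) 0/1 array; leaf ``i`` of ``adj`` takes
    row ``i``.  The score is the weighted number of state changes required,
    summed over characters.
    """
    chars = np.asarray(chars)
    n_leaves, n_chars = chars.shape
    if weights is None:
        weights = np.ones(n_chars)
    root_leaf = min(k for k in adj if len(adj[k]) == 1)
    post, children = _rooted_orders(adj, root_leaf)
    # state sets as 2-bit masks: 1 -> {0}, 2 -> {1}
    states = {}
    score = np.zeros(n_chars)
    for node in post:
        if node < n_leaves:
            states[node] = (chars[node] + 1).astype(np.uint8)
        else:
            acc = states[children[node][0]]
            for k in children[node][1:]:
                inter = acc & states[k]
                union_needed = inter == 0
                score += union_needed
                acc = np.where(union_needed, acc | states[k], inter).astype(np.uint8)
            states[node] = acc
    # close the edge to the leaf the tree was hung from
    score += (states[adj[root_leaf][0]] & (chars[root_leaf] + 1)) == 0
    return float((score * weights).sum())


def nni_neighbors(adj: Adjacency) -> list[Adjacency]:
    """All nearest-neighbor-interchange rearrangements of a topology."""
    out = []
    for u, v in _edges(adj):
        if len(adj[u]) != 3 or len(adj[v]) != 3:
            continue  # only internal edges
        a, b = [x for x in adj[u] if x != v]
        c, d = [x for x in adj[v] if x != u]
        for x, y in ((b, c), (b, d)):
            t = _copy(adj)
            t[u].remove(x); t[v].remove(y)
            t[u].append(y); t[v].append(x)
            t[x].remove(u); t[x].append(v)
            t[y].remove(v); t[y].append(u)
            out.append(t)
    return out


def newick(adj: Adjacency, names: Sequence[str]) -> str:
    """Canonical Newick string (rooted at the lexicographically first leaf,
    sibling subtrees sorted), usable for isomorphism comparison."""
    n_leaves = sum(1 for k in adj if len(adj[k]) == 1)
    root = min(range(n_leaves), key=lambda i: str(names[i]))

    def sub(parent: int, node: int) -> str:
        if len(adj[node]) == 1:
            return str(names[node])
        parts = sorted(sub(node, k) for k in adj[node] if k != parent)
        return "(" + ",".join(parts) + ")"

    return f"({names[root]},{sub(root, adj[root][0])});"


def bipartitions(adj: Adjacency, names: Sequence[str]) -> set[frozenset]:
    """Nontrivial splits of the tree, each as the leaf-name side not
    containing the first leaf."""
    n_leaves = sum(1 for k in adj if len(adj[k]) == 1)
    out = set()
    for u, v in _edges(adj):
        if len(adj[u]) == 1 or len(adj[v]) == 1:
            continue
        # leaves on v's side of edge u-v
        side = set()
        stack = [(u, v)]
        while stack:
            p, n = stack.pop()
            if len(adj[n]) == 1:
                side.add(n)
            stack.extend((n, k) for k in adj[n] if k != p)
        if 0 in side:
            side = set(range(n_leaves)) - side
        out.add(frozenset(names[i] for i in side))
    return out


# ---------------------------------------------------------------------------
# Character matrix


def build_character_matrix(
    vaf_matrix: pd.DataFrame,
    consequence: Mapping,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Binary presence/absence character matrix for tree building.

    Rows of ``vaf_matrix`` (alterations x samples, VAF values) are kept when
    the alteration is not silent and is present (VAF > 0) in at least
    ``min_samples`` samples.  Requires >= 3 samples.
    """
    if vaf_matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for an unrooted topology")
    binary = (vaf_matrix > 0).astype(int)
    non_silent = [k for k in binary.index if consequence.get(k, "unknown") != "silent"]
    binary = binary.loc[non_silent]
    return binary.loc[binary.sum(axis=1) >= min_samples]


# ---------------------------------------------------------------------------
# Search


@dataclass
class PhyloTree:
    """Best-scoring unrooted tree with its character data."""

    adj: Adjacency
    leaf_names: list[str]
    score: float
    co_optimal: list[str] = field(default_factory=list)

    def newick(self) -> str:
        return newick(self.adj, self.leaf_names)

    def bipartitions(self) -> set[frozenset]:
        return bipartitions(self.adj, self.leaf_names)


def _hill_climb(adj: Adjacency, chars: np.ndarray,
                weights: np.ndarray | None) -> tuple[Adjacency, float]:
    cur, cur_score = adj, fitch_score(adj, chars, weights)
    while True:
        best, best_score = None, cur_score
        for t in nni_neighbors(cur):
            s = fitch_score(t, chars, weights)
            if s < best_score:
                best, best_score = t, s
        if best is None:
            return cur, cur_score
        cur, cur_score = best, best_score


def _stepwise_addition(chars: np.ndarray, order: np.ndarray) -> Adjacency:
    n_leaves = chars.shape[0]
    relabel = {0: int(order[0]), 1: int(order[1]), 2: int(order[2])}
    adj = _star3(n_leaves)
    adj = {relabel.get(k, k): [relabel.get(x, x) for x in v]
           for k, v in adj.items()}
    next_internal = n_leaves + 1
    for leaf in order[3:]:
        best, best_score = None, np.inf
        for edge in _edges(adj):
            t = _attach_leaf(adj, int(leaf), edge, next_internal)
            s = fitch_score(t, chars[:, :])  # score with only placed leaves?
            if s < best_score:
                best, best_score = t, s
        adj = best
        next_internal += 1
    return adj


def parsimony_ratchet(
    matrix: pd.DataFrame,
    iterations: int = 200,
    seed: int = 0,
    upweight_frac: float = 0.25,
    upweight: float = 2.0,
) -> PhyloTree:
    """Parsimony-ratchet search for the maximum-parsimony unrooted tree.

    Each iteration upweights a random ``upweight_frac`` of the characters,
    hill-climbs (NNI) under the perturbed weights from the incumbent, then
    hill-climbs under the original weights.  The best tree (ties broken by
    lexicographically smallest canonical Newick) is returned; all co-optimal
    trees encountered are retrievable via ``co_optimal``.  Deterministic for
    a fixed seed.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    # canonical column order: the search (and its tie-breaks) must not
    # depend on how the caller happened to order the samples
    matrix = matrix[sorted(matrix.columns, key=str)]
    names = [str(c) for c in matrix.columns]
    chars = matrix.to_numpy(int).T  # leaves x characters
    n_leaves = len(names)
    if n_leaves < 3:
        raise ValueError("need >= 3 samples")
    rng = np.random.default_rng(seed)
    if n_leaves == 3:
        adj = _star3(3)
        return PhyloTree(adj, names, fitch_score(adj, chars),
                         [newick(adj, names)])
    if n_leaves <= 7:
        # small instances are solved exactly: enumerate every topology
        best_score = np.inf
        opt: dict[str, Adjacency] = {}
        for adj in enumerate_topologies(n_leaves):
            s = fitch_score(adj, chars)
            if s < best_score:
                best_score, opt = s, {newick(adj, names): adj}
            elif s == best_score:
                opt.setdefault(newick(adj, names), adj)
        key = min(opt)
        return PhyloTree(opt[key], names, best_score, sorted(opt))

    start = _stepwise_addition(chars, rng.permutation(n_leaves))
    best, best_score = _hill_climb(start, chars, None)
    opt: dict[str, Adjacency] = {newick(best, names): best}
    n_chars = chars.shape[1]
    for _ in range(iterations):
        w = np.ones(n_chars)
        w[rng.random(n_chars) < upweight_frac] = upweight
        t, _ = _hill_climb(best, chars, w)
        t, s = _hill_climb(t, chars, None)
        if s < best_score:
            best, best_score = t, s
            opt = {newick(t, names): t}
        elif s == best_score:
            opt.setdefault(newick(t, names), t)
    key = min(opt)
    return PhyloTree(opt[key], names, best_score, sorted(opt))


def exhaustive_best_score(matrix: pd.DataFrame) -> float:
    """Minimum parsimony score over *all* topologies (oracle; <= ~8 leaves)."""
    chars = matrix.to_numpy(int).T
    return min(fitch_score(adj, chars)
               for adj in enumerate_topologies(chars.shape[0]))


# ---------------------------------------------------------------------------
# Branch assignment


HOMOPLASTIC = "homoplastic"


def assign_branch_alterations(
    tree: PhyloTree,
    snv_matrix: pd.DataFrame,
    cna_matrix: pd.DataFrame | None = None,
    outgroup: str = "germline",
) -> pd.DataFrame:
    """Assign alterations to tree branches by their presence sets.

    The tree is rooted at the ``outgroup`` leaf (an all-zero pseudo-germline
    included in the search matrix); each matrix row is assigned to the edge
    whose downstream leaf set equals the row's presence set, or flagged
    ``homoplastic`` when no edge matches.  CNA rows, when given, are mapped
    post hoc onto the same tree.

    Returns a table ``alteration, kind, branch, downstream`` where ``branch``
    is the child node of the edge ("<node>" or ``homoplastic``) and
    ``downstream`` the sorted downstream samples.
    """
    names = tree.leaf_names
    if outgroup not in names:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    root = names.index(outgroup)
    _, children = _rooted_orders(tree.adj, root)
    down: dict[int, frozenset] = {}

    def leafset(node: int) -> frozenset:
        if node < len(names):
            s = frozenset({names[node]})
        else:
            s = frozenset().union(*(leafset(k) for k in children[node]))
        down[node] = s
        return s

    leafset(tree.adj[root][0])
    by_set = {}
    for node, s in down.items():
        by_set.setdefault(s - {outgroup}, node)

    rows = []

    def place(matrix: pd.DataFrame, kind: str) -> None:
        for alt, row in matrix.iterrows():
            present = frozenset(str(c) for c in matrix.columns if row[c] > 0)
            node = by_set.get(present)
            rows.append({
                "alteration": alt,
                "kind": kind,
                "branch": str(node) if node is not None else HOMOPLASTIC,
                "downstream": ",".join(sorted(present)),
            })

    place(snv_matrix.drop(columns=[outgroup], errors="ignore"), "snv")
    if cna_matrix is not None:
        place(cna_matrix.drop(columns=[outgroup], errors="ignore"), "cna")
    return pd.DataFrame(rows)
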