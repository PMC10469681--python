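"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own tree code: Newick is
parsed with dendropy directly, bipartitions are enumerated by deleting each
edge of a networkx graph and reading off connected components, parsimony and
likelihood oracles enumerate internal labelings exhaustively.
"""

from __future__ import annotations

import math

import dendropy
import networkx as nx
import numpy as np
import pytest


# ---------------------------------------------------------------------------
# random trees
# ---------------------------------------------------------------------------


def random_tree_newick(rng: np.random.Generator, n_leaves: int, prefix: str = "L") -> str:
    """A random rooted binary tree with uniform random branch lengths."""
    nodes = [f"{prefix}{i}:{rng.uniform(0.05, 0.5):.6f}" for i in range(1, n_leaves + 1)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.05, 0.5):.6f}")
    return f"({nodes[0]},{nodes[1]});"


# ---------------------------------------------------------------------------
# graph-based bipartition oracle
# ---------------------------------------------------------------------------


def _graph_of(newick: str):
    dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    g = nx.Graph()
    label = {}
    for nd in dt.preorder_node_iter():
        g.add_node(id(nd))
        if nd.is_leaf():
            label[id(nd)] = nd.taxon.label
        if nd.parent_node is not None:
            g.add_edge(id(nd.parent_node), id(nd))
    return g, label


def brute_edge_sides(newick: str) -> list[frozenset]:
    """All leaf-set sides obtainable by deleting one edge (unrooted reading)."""
    g, label = _graph_of(newick)
    sides = set()
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        for comp in nx.connected_components(g):
            leaves = frozenset(label[x] for x in comp if x in label)
            if leaves:
                sides.add(leaves)
        g.add_edge(u, v)
    return sorted(sides, key=lambda s: (len(s), tuple(sorted(s))))


def brute_is_monophyletic(newick: str, focal: set) -> bool:
    focal = frozenset(focal)
    all_leaves = frozenset().union(*brute_edge_sides(newick))
    if len(focal) == 1 or focal == all_leaves:
        return True
    return focal in set(brute_edge_sides(newick))


def brute_minimal_spanning_side(newick: str, focal: set) -> frozenset:
    focal = frozenset(focal)
    sides = brute_edge_sides(newick)
    all_leaves = frozenset().union(*sides)
    containing = [s for s in sides if focal <= s]
    if not containing:
        return all_leaves
    best = min(len(s) for s in containing)
    return min((s for s in containing if len(s) == best), key=lambda s: tuple(sorted(s)))


def brute_nontrivial_splits(newick: str) -> set[frozenset]:
    """Canonical nontrivial splits (frozenset of both sides) for RF comparison."""
    sides = brute_edge_sides(newick)
    all_leaves = frozenset().union(*sides)
    out = set()
    for s in sides:
        t = all_leaves - s
        if len(s) >= 2 and len(t) >= 2:
            out.add(frozenset((s, t)))
    return out


# ---------------------------------------------------------------------------
# parsimony / likelihood enumeration oracles
# ---------------------------------------------------------------------------


def _rooted_structure(newick: str):
    dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    internals = [nd for nd in dt.preorder_node_iter() if not nd.is_leaf()]
    return dt, internals


def brute_fitch_min(newick: str, states: dict[str, int]) -> int:
    """Minimum change count over all 2^(#internal) labelings."""
    dt, internals = _rooted_structure(newick)
    best = math.inf
    for mask in range(2 ** len(internals)):
        lab = {id(nd): (mask >> i) & 1 for i, nd in enumerate(internals)}
        for nd in dt.leaf_node_iter():
            lab[id(nd)] = states[nd.taxon.label]
        changes = sum(
            lab[id(nd)] != lab[id(nd.parent_node)]
            for nd in dt.preorder_node_iter()
            if nd.parent_node is not None
        )
        best = min(best, changes)
    return int(best)


def brute_mk_loglik(
    newick: str, states: dict[str, int], gain: float, loss: float, prior1: float
) -> float:
    """Likelihood by summing over every internal state assignment."""
    dt, internals = _rooted_structure(newick)
    r = gain + loss
    def P(i, j, t):
        if r == 0:
            return 1.0 if i == j else 0.0
        e = math.exp(-r * t)
        pi = (loss / r, gain / r)
        return pi[j] + (1.0 - pi[j]) * e if i == j else pi[j] * (1.0 - e)
    prior = (1.0 - prior1, prior1)
    total = 0.0
    for mask in range(2 ** len(internals)):
        lab = {id(nd): (mask >> i) & 1 for i, nd in enumerate(internals)}
        for nd in dt.leaf_node_iter():
            lab[id(nd)] = states[nd.taxon.label]
        term = prior[lab[id(dt.seed_node)]]
        for nd in dt.preorder_node_iter():
            if nd.parent_node is not None:
                term *= P(lab[id(nd.parent_node)], lab[id(nd)], nd.edge.length or 0.0)
        total += term
    return math.log(total)


# ---------------------------------------------------------------------------
# rank-based oracle
# ---------------------------------------------------------------------------


def brute_spearman_rho(x, y) -> float:
    """Definition-based Spearman: explicit average ranks, then Pearson."""
    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
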