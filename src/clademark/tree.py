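"""Tree primitives: Newick I/O, bipartitions, monophyly queries, NJ, Robinson-Foulds.

A :class:`PhyloTree` wraps a :mod:`dendropy` tree and exposes the small set of
unrooted-tree operations the screening pipeline needs.  Monophyly is defined on
the *unrooted* tree via edge bipartitions: a leaf set is monophyletic iff it is
one side of some edge's bipartition.  A rooted input (root of degree 2) is
treated as unrooted by suppressing the root for all bipartition queries.
"""

from __future__ import annotations

import io
import logging
from typing import Iterable, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "Bipartition",
    "NewickParseError",
    "parse_newick",
    "neighbor_joining",
    "rf_distance",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed; message names the position."""


class Bipartition:
    """A canonical split of a leaf set: stored as the smaller side.

    Ties in side size are broken by the lexicographically first sorted
    label tuple, so equal splits always compare (and hash) equal.
    """

    __slots__ = ("side", "_key")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a = frozenset(side_a)
        b = frozenset(side_b)
        if not a or not b:
            raise ValueError("both sides of a bipartition must be nonempty")
        if a & b:
            raise ValueError("bipartition sides overlap")
        if len(a) < len(b) or (len(a) == len(b) and tuple(sorted(a)) < tuple(sorted(b))):
            self.side = a
        else:
            self.side = b
        self._key = tuple(sorted(self.side))

    def __eq__(self, other):
        return isinstance(other, Bipartition) and self._key == other._key

    def __hash__(self):
        return hash(self._key)

    def __repr__(self):
        return f"Bipartition({set(self._key)!r})"


class PhyloTree:
    """A (possibly unrooted) tree with uniquely labeled leaves and branch lengths.

    Branch lengths absent from the source Newick default to 0.0.  Leaf labels
    must be unique; internal node labels are ignored on read.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        self._leaf_set = frozenset(labels)
        for e in dtree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValueError("negative branch length")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from None
        if dtree.seed_node is None or not dtree.seed_node.child_nodes():
            raise NewickParseError("malformed Newick: no tree found")
        return cls(dtree)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        )
        return s.strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- basic properties ---------------------------------------------

    @property
    def leaf_labels(self) -> frozenset:
        return self._leaf_set

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_set)

    @property
    def is_rooted(self) -> bool:
        """True iff the root has exactly two children (a rooted bifurcation)."""
        return len(self._tree.seed_node.child_nodes()) == 2

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self._tree.preorder_edge_iter())

    # -- bipartitions --------------------------------------------------

    def _edge_sides(self) -> list[frozenset]:
        """Leaf sets below each edge of the unrooted tree, deduplicated.

        For a degree-2 root the two root-adjacent edges describe the same
        split and are collapsed into one.
        """
        sides = []
        seen = set()
        below: dict = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                below[nd] = frozenset([nd.taxon.label])
            else:
                below[nd] = frozenset().union(*(below[c] for c in nd.child_nodes()))
        root = self._tree.seed_node
        for nd in self._tree.preorder_node_iter():
            if nd is root:
                continue
            s = below[nd]
            key = min((tuple(sorted(s)), tuple(sorted(self._leaf_set - s))))
            if key in seen:
                continue
            seen.add(key)
            sides.append(s)
        return sides

    def bipartitions(self, include_trivial: bool = False) -> set[Bipartition]:
        """All edge bipartitions of the unrooted tree.

        Trivial splits (a single leaf against the rest) are excluded unless
        requested.
        """
        out = set()
        for s in self._edge_sides():
            if not include_trivial and (len(s) <= 1 or len(self._leaf_set - s) <= 1):
                continue
            if s == self._leaf_set:
                continue
            out.add(Bipartition(s, self._leaf_set - s))
        return out

    def _check_focal(self, focal: Iterable[str]) -> frozenset:
        f = frozenset(focal)
        if not f:
            raise ValueError("focal leaf set is empty")
        missing = sorted(f - self._leaf_set)
        if missing:
            raise KeyError(f"labels not in tree: {missing}")
        return f

    def is_monophyletic(self, focal: Iterable[str]) -> bool:
        """True iff some edge bipartitions the leaves into exactly (focal, rest).

        Singletons and the full leaf set are vacuously monophyletic.
        """
        f = self._check_focal(focal)
        if len(f) == 1 or f == self._leaf_set:
            return True
        for s in self._edge_sides():
            if s == f or self._leaf_set - s == f:
                return True
        return False

    def minimal_spanning_side(self, focal: Iterable[str]) -> frozenset:
        """Smallest edge-bipartition side containing the focal leaves.

        Returns the full leaf set when no proper side contains the focal set.
        Ties in size are broken by canonical (lexicographic) order.
        """
        f = self._check_focal(focal)
        best = self._leaf_set
        best_key = (len(best), tuple(sorted(best)))
        for s in self._edge_sides():
            for side in (s, self._leaf_set - s):
                if f <= side:
                    key = (len(side), tuple(sorted(side)))
                    if key < best_key:
                        best, best_key = side, key
        return frozenset(best)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (plain or quoted labels) into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: symmetric difference of nontrivial bipartitions."""
    if t1.leaf_labels != t2.leaf_labels:
        raise ValueError(
            "leaf sets differ: "
            f"only-in-first={sorted(t1.leaf_labels - t2.leaf_labels)}, "
            f"only-in-second={sorted(t2.leaf_labels - t1.leaf_labels)}"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Neighbor joining on a symmetric distance matrix.

    Exact on additive matrices (path lengths reproduce the input).  Negative
    branch-length estimates are clamped to zero with a logged warning.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if len(labels) != D.shape[0]:
        raise ValueError("label count does not match matrix size")
    if D.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix diagonal must be zero")

    tnode = nj(DistanceMatrix(D, ids=list(labels)), neg_as_zero=False)
    n_neg = 0
    for node in tnode.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_neg += 1
    if n_neg:
        logger.warning("neighbor_joining: clamped %d negative branch lengths to 0", n_neg)
    buf = io.StringIO()
    tnode.write(buf)
    return PhyloTree.from_newick(buf.getvalue())
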