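"""Ultrametric (clock) trees.

A thin wrapper over :class:`dendropy.Tree` that enforces the clock
constraint all downstream analyses rely on: every leaf is equidistant
from the root, so each node carries a well-defined *height* (age above
the present, in expected substitutions per site throughout this
package).  The wrapper caches node heights, validates ultrametricity on
construction, and exposes the handful of queries the lineage-assignment
and species-delimitation code needs (root split, branching heights,
clusters below a height threshold).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy

__all__ = [
    "UltrametricTree",
    "UltrametricityError",
    "TreeError",
]

#: relative tolerance on the spread of leaf depths, as a fraction of tree height
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Malformed tree input (no branch lengths, empty, unrooted...)."""


class UltrametricityError(TreeError):
    """Leaf depths spread beyond tolerance for a clock tree."""


class UltrametricTree:
    """A rooted binary clock tree with node heights.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree`` with branch lengths on every
        non-root edge.  Polytomies are resolved deterministically
        (zero-length splits, children ordered by sorted leaf label).
    rtol:
        Relative ultrametricity tolerance: the max spread of leaf
        depths must not exceed ``rtol`` times the tree height.
    """

    def __init__(self, tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL):
        if tree.seed_node is None or not tree.leaf_nodes():
            raise TreeError("empty tree")
        tree.is_rooted = True
        self._tree = tree
        self._resolve_polytomies()
        self._compute_heights(rtol)

    # ------------------------------------------------------------------
    # construction helpers

    @classmethod
    def from_newick(cls, newick: str, rtol: float = ULTRAMETRIC_RTOL) -> "UltrametricTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls(tree, rtol=rtol)

    def _resolve_polytomies(self) -> None:
        # Deterministic binary resolution: repeatedly split off the two
        # children whose smallest descendant labels sort first, joined by a
        # zero-length edge.  Leaves label order to break every tie.
        for node in list(self._tree.preorder_node_iter()):
            while len(node.child_nodes()) > 2:
                kids = sorted(node.child_nodes(), key=_min_leaf_label)
                a, b = kids[0], kids[1]
                joint = dendropy.Node(edge_length=0.0)
                node.remove_child(a)
                node.remove_child(b)
                joint.add_child(a)
                joint.add_child(b)
                node.add_child(joint)

    def _compute_heights(self, rtol: float) -> None:
        root = self._tree.seed_node
        depth = {root: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise TreeError(f"missing branch length above node {_label(node)!r}")
            depth[node] = depth[node.parent_node] + float(node.edge.length)
        leaf_depths = [depth[lf] for lf in self._tree.leaf_node_iter()]
        height = max(leaf_depths)
        spread = height - min(leaf_depths)
        if height > 0 and spread > rtol * height:
            raise UltrametricityError(
                f"tree is not ultrametric: leaf depth spread {spread:.3g} "
                f"exceeds tolerance {rtol:.1g} x height {height:.3g}"
            )
        for node in self._tree.preorder_node_iter():
            node.height = 0.0 if node.is_leaf() else height - depth[node]
        self._height = height

    # ------------------------------------------------------------------
    # basic queries

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root_height(self) -> float:
        return float(self._tree.seed_node.height)

    @property
    def n_leaves(self) -> int:
        return len(self._tree.leaf_nodes())

    def leaf_labels(self) -> list[str]:
        return [_label(lf) for lf in self._tree.leaf_node_iter()]

    def branching_heights(self) -> list[float]:
        """Heights of all internal nodes, ascending (most recent first)."""
        return sorted(
            float(n.height)
            for n in self._tree.preorder_internal_node_iter()
        )

    def root_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """Leaf-label sets of the two subtrees of the root."""
        kids = self._tree.seed_node.child_nodes()
        if len(kids) != 2:
            raise TreeError("root is not bifurcating")
        return tuple(
            frozenset(_label(lf) for lf in k.leaf_iter()) for k in kids
        )  # type: ignore[return-value]

    def clusters_at(self, threshold: float) -> list[frozenset[str]]:
        """Maximal subtrees whose root height is <= ``threshold``.

        Each lineage crossing the threshold roots one cluster; leaves
        hanging directly off deeper nodes form singleton clusters.  The
        clusters partition the leaf set.
        """
        root = self._tree.seed_node
        clusters: list[frozenset[str]] = []

        def walk(node):
            if node.height <= threshold:
                clusters.append(frozenset(_label(lf) for lf in node.leaf_iter()))
            else:
                for child in node.child_nodes():
                    walk(child)

        walk(root)
        return clusters

    # ------------------------------------------------------------------
    # serialization

    def to_newick(self) -> str:
        # re-derive edge lengths from heights so writes are exact
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = node.parent_node.height - node.height
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        )
        return s.strip() + "\n"

    def __repr__(self) -> str:  # pragma: no cover - debug nicety
        return f"UltrametricTree(n_leaves={self.n_leaves}, height={self.root_height:.6g})"


def _label(node) -> str:
    if node.taxon is not None:
        return str(node.taxon.label)
    return str(node.label)


def _min_leaf_label(node) -> str:
    return min(_label(lf) for lf in node.leaf_iter())


def build_tree_from_heights(
    merges: Sequence[tuple[float, object, object]],
    leaf_labels: Iterable[str],
) -> UltrametricTree:
    """Assemble an :class:`UltrametricTree` from a merge list.

    ``merges`` is a sequence of ``(height, left, right)`` triples where
    ``left``/``right`` are either leaf labels (str) or indices of earlier
    merges (int).  Used by the coalescent simulator and by UPGMA.
    """
    taxa = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    for lab in leaf_labels:
        n = dendropy.Node(taxon=taxa.new_taxon(label=lab))
        n.height = 0.0
        nodes[lab] = n
    merged: list[dendropy.Node] = []
    for height, left, right in merges:
        ln = merged[left] if isinstance(left, int) else nodes[left]
        rn = merged[right] if isinstance(right, int) else nodes[right]
        parent = dendropy.Node()
        parent.height = float(height)
        for child in (ln, rn):
            parent.add_child(child)
            child.edge.length = parent.height - child.height
        merged.append(parent)
    if not merged:
        raise TreeError("need at least one merge to build a tree")
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = merged[-1]
    return UltrametricTree(tree)
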