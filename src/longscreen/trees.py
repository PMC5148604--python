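"""Rooted phylogenies: newick I/O, depth/path bookkeeping, and pruning.

The tree is the source of all covariance structure in the screen.  We wrap a
:class:`dendropy.Tree` in a thin, immutable-feeling container that exposes the
three quantities phylogenetic regression needs for a set of tips:

* ``T_i``   — root-to-tip depth of tip *i*,
* ``t_ij``  — depth of the most recent common ancestor of tips *i, j*
  (the shared root-to-MRCA path length),
* ``d_ij`` — patristic (tip-to-tip path) distance.

These satisfy ``d_ij = T_i + T_j - 2 t_ij``.
"""

from __future__ import annotations

import dendropy
import numpy as np


class NewickParseError(ValueError):
    """Malformed newick input (unbalanced parentheses, duplicate tips, ...)."""


class PhyloTree:
    """A rooted tree with branch lengths and uniquely labeled tips."""

    def __init__(self, tree: dendropy.Tree, rooted: bool = True):
        self._tree = tree
        self.rooted = rooted
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickParseError(f"duplicate tip labels: {dups}")
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        self.tip_labels: list[str] = labels

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, text: str, rooted: bool = True) -> "PhyloTree":
        depth = 0
        for offset, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError(
                        f"unbalanced ')' at offset {offset}")
        if depth != 0:
            raise NewickParseError(
                f"{depth} unclosed '(' at end of input (length {len(text)})")
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(str(exc)) from exc
        return cls(tree, rooted=rooted)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g")
        return s.strip() + "\n"

    # ------------------------------------------------------------- geometry
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        self._tree.calc_node_root_distances(
            return_leaf_distances_only=False)
        return {leaf.taxon.label: float(leaf.root_distance)
                for leaf in self._tree.leaf_node_iter()}

    def path_matrices(self, labels: list[str] | None = None):
        """Return ``(labels, t_ij, d_ij, T)`` aligned to ``labels``.

        ``t_ij`` is the shared root-to-MRCA path-length matrix (diagonal =
        depths), ``d_ij`` the patristic distance matrix, ``T`` the depth
        vector.
        """
        if labels is None:
            labels = list(self.tip_labels)
        missing = set(labels) - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        tmat = np.zeros((n, n))
        # postorder sweep: tips meeting first at a node share that node's depth
        tipsets: dict[int, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                tipsets[id(node)] = [idx[lab]] if lab in idx else []
                continue
            child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
            depth = float(node.root_distance)
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            tmat[i, j] = tmat[j, i] = depth
            merged: list[int] = []
            for cs in child_sets:
                merged.extend(cs)
            tipsets[id(node)] = merged
        depths = self.depths()
        T = np.array([depths[lab] for lab in labels])
        np.fill_diagonal(tmat, T)
        dmat = T[:, None] + T[None, :] - 2 * tmat
        np.fill_diagonal(dmat, 0.0)
        return labels, tmat, dmat, T

    def prune(self, labels) -> "PhyloTree":
        """Tree restricted to ``labels``; patristic distances are preserved."""
        labels = list(labels)
        missing = set(labels) - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        if len(labels) < 2:
            raise ValueError("cannot prune to fewer than 2 tips")
        sub = self._tree.extract_tree_with_taxa_labels(
            labels, suppress_unifurcations=True)
        return PhyloTree(sub, rooted=self.rooted)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips}, rooted={self.rooted})"


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree, preserving branch lengths to full precision."""
    return tree.to_newick()


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree))
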