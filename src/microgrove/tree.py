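"""Rooted phylogenetic trees with branch lengths.

A thin array-backed wrapper around :mod:`dendropy` trees.  The wrapper caches
the branch/tip incidence structure that UniFrac and Faith's phylogenetic
diversity both consume: one row per edge (the edge *above* each non-root
node), one column per tip, ``incidence[b, t]`` true when tip ``t`` descends
through edge ``b``.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

from .errors import FormatError, InvariantError

__all__ = ["PhyloTree", "read_tree", "write_tree"]


class PhyloTree:
    """Rooted tree with non-negative branch lengths and unique tip labels."""

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise InvariantError("duplicate tip labels in tree")
        self.tip_labels: list[str] = labels
        self._tip_index = {lab: i for i, lab in enumerate(labels)}
        self._edges_built = False
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise InvariantError(f"negative branch length {edge.length}")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"newick parse error: {exc}") from exc
        return cls(dtree)

    def to_newick(self) -> str:
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- incidence structure ----------------------------------------------
    def _build_edges(self) -> None:
        """Postorder pass filling branch lengths and tip incidence.

        A root edge with positive length is kept as a branch ancestral to
        every tip (it is shared by any two non-empty communities), matching
        the common UniFrac implementations.
        """
        n_tips = len(self.tip_labels)
        lengths: list[float] = []
        rows: list[np.ndarray] = []
        root = self._dtree.seed_node
        masks: dict[int, np.ndarray] = {}
        for node in self._dtree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(n_tips, dtype=bool)
                mask[self._tip_index[node.taxon.label]] = True
            else:
                mask = np.zeros(n_tips, dtype=bool)
                for child in node.child_nodes():
                    mask |= masks[id(child)]
            masks[id(node)] = mask
            if node is not root or (node.edge.length or 0.0) > 0:
                lengths.append(node.edge.length or 0.0)
                rows.append(mask)
        self._branch_lengths = np.asarray(lengths, dtype=float)
        self._incidence = (
            np.vstack(rows) if rows else np.zeros((0, n_tips), dtype=bool)
        )
        self._edges_built = True

    @property
    def branch_lengths(self) -> np.ndarray:
        if not self._edges_built:
            self._build_edges()
        return self._branch_lengths

    def incidence(self, taxa: Sequence[str] | None = None) -> np.ndarray:
        """Edge × taxon incidence, columns ordered as ``taxa``.

        Raises if any requested taxon is not a tip of the tree.
        """
        if not self._edges_built:
            self._build_edges()
        if taxa is None:
            return self._incidence
        missing = [t for t in taxa if t not in self._tip_index]
        if missing:
            raise InvariantError(f"taxa absent from tree: {missing[:10]}")
        cols = [self._tip_index[t] for t in taxa]
        return self._incidence[:, cols]

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips}, total_bl={self.total_branch_length:.3g})"


def read_tree(path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
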