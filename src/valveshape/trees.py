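"""Rooted phylogeny wrapper used by the comparative analyses.

Trees are parsed with dendropy and normalized on construction: tip labels
must be unique, polytomies are resolved deterministically (left-first) with
epsilon-length branches, and zero/absent branch lengths are replaced by
epsilon so that contrast standardization and squared-change weights are
always defined.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import dendropy

from .data import ValidationError

#: branch length inserted when resolving polytomies or replacing zero lengths
EPSILON = 1e-8


class NewickParseError(ValueError):
    pass


@dataclass
class PhyloTree:
    """A rooted, binary tree with strictly positive branch lengths."""

    tree: dendropy.Tree
    epsilon: float = EPSILON

    def __post_init__(self):
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dups}")
        self._resolve_polytomies()
        self._fix_branch_lengths()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, source: str, epsilon: float = EPSILON) -> "PhyloTree":
        """Parse a Newick string or file path."""
        try:
            if "(" in source or ";" in source:
                tree = dendropy.Tree.get(data=source, schema="newick")
            else:
                tree = dendropy.Tree.get(path=source, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"cannot parse Newick input: {exc}") from exc
        return cls(tree, epsilon=epsilon)

    # -- normalization ----------------------------------------------------
    def _resolve_polytomies(self):
        # left-first: repeatedly fuse the first two children into a new node
        # attached with an epsilon branch, preserving child order otherwise.
        for node in list(self.tree.preorder_node_iter()):
            while len(node.child_nodes()) > 2:
                children = node.child_nodes()
                a, b = children[0], children[1]
                node.remove_child(a)
                node.remove_child(b)
                merged = dendropy.Node()
                merged.edge.length = 0.0  # replaced by epsilon below
                merged.add_child(a)
                merged.add_child(b)
                node.insert_child(0, merged)

    def _fix_branch_lengths(self):
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue  # root edge carries no information here
            if edge.length is None or edge.length <= 0:
                edge.length = self.epsilon

    # -- queries ----------------------------------------------------------
    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def branch_lengths(self) -> dict[str, float]:
        return {leaf.taxon.label: leaf.edge.length for leaf in self.tree.leaf_node_iter()}

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2 for n in self.tree.preorder_internal_node_iter()
        )

    def prune_to(self, labels) -> "PhyloTree":
        """Return a copy pruned to ``labels``; extra tips are dropped."""
        labels = set(labels)
        present = set(self.tip_labels)
        missing = labels - present
        if missing:
            raise ValidationError(f"tips not in tree: {sorted(missing)}")
        clone = dendropy.Tree(self.tree)
        clone.retain_taxa_with_labels(sorted(labels))
        return PhyloTree(clone, epsilon=self.epsilon)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def read_newick(path_or_string: str, epsilon: float = EPSILON) -> PhyloTree:
    """Read a Newick tree from a file path or literal string."""
    return PhyloTree.from_newick(str(path_or_string), epsilon=epsilon)
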