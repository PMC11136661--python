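"""Rooted species trees with stable branch identifiers.

Leaf branches are addressed by the taxon label; internal branches get
letters (A, B, C, ...) assigned in post-order, matching the convention
of labelling internal tree branches for gene-flow summaries.
"""

from __future__ import annotations

import string

import dendropy


class SpeciesTree:
    """A rooted binary species tree wrapping a :class:`dendropy.Tree`."""

    def __init__(self, tree: dendropy.Tree, outgroup: str | None = None):
        self.tree = tree
        self.outgroup = outgroup
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf labels")
        if outgroup is not None and outgroup not in leaves:
            raise ValueError(f"outgroup {outgroup!r} not a leaf of the tree")
        self._branches: dict[str, dendropy.Node] = {}
        letters = iter(self._letter_ids())
        for node in tree.postorder_node_iter():
            if node is tree.seed_node:
                continue
            if node.is_leaf():
                self._branches[node.taxon.label] = node
            else:
                self._branches[next(letters)] = node

    @staticmethod
    def _letter_ids():
        for ch in string.ascii_uppercase:
            yield ch
        for a in string.ascii_uppercase:
            for b in string.ascii_uppercase:
                yield a + b

    @classmethod
    def from_newick(cls, newick: str, outgroup: str | None = None) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        tree.is_rooted = True
        return cls(tree, outgroup=outgroup)

    @classmethod
    def from_file(cls, path: str, outgroup: str | None = None) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), outgroup=outgroup)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def branch_ids(self) -> list[str]:
        """All addressable branch ids (leaf labels + internal letters)."""
        return list(self._branches)

    @property
    def internal_branch_ids(self) -> list[str]:
        return [b for b, n in self._branches.items() if not n.is_leaf()]

    def descendants(self, branch_id: str) -> list[str]:
        """Leaf labels below a branch (a leaf branch yields itself)."""
        node = self._branches[branch_id]
        if node.is_leaf():
            return [node.taxon.label]
        return [lf.taxon.label for lf in node.leaf_iter()]

    def sister(self, branch_id: str) -> str | None:
        """Branch id of the sister branch, or None for a child of the root
        with more than one sibling (non-binary root)."""
        node = self._branches[branch_id]
        parent = node.parent_node
        sibs = [c for c in parent.child_nodes() if c is not node]
        if len(sibs) != 1:
            return None
        return self._id_of(sibs[0])

    def _id_of(self, node: dendropy.Node) -> str:
        for bid, n in self._branches.items():
            if n is node:
                return bid
        raise KeyError("node has no branch id (root?)")

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()
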