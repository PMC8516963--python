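"""Rooted species trees.

A thin wrapper around :class:`dendropy.Tree` that fixes the conventions the
rest of the package relies on: every node carries a stable string id (tip ids
are the taxon labels, internal ids are assigned ``nK`` in postorder), branch
lengths are expected substitutions per site, and an optional set of nodes may
be flagged as belonging to a long-branch clade.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

import dendropy

__all__ = ["SpeciesTree"]


class SpeciesTree:
    """A rooted (binary, except possibly at the root) species tree.

    Parameters
    ----------
    tree
        A rooted ``dendropy.Tree``.  Tip labels must be unique and branch
        lengths non-negative (``None`` edge lengths are treated as 0 for the
        root edge only).
    long_clade_root
        Node id of the subtree flagged as the long-branch clade, or ``None``.
    """

    def __init__(self, tree: dendropy.Tree, long_clade_root: Optional[str] = None):
        self._tree = tree
        self._tree.is_rooted = True
        self._assign_ids()
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels must be unique")
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                if node.edge.length is None:
                    node.edge.length = 0.0
                if node.edge.length < 0:
                    raise ValueError("branch lengths must be non-negative")
        self.long_clade_root = long_clade_root
        if long_clade_root is not None and long_clade_root not in self._by_id:
            raise ValueError(f"unknown long-clade root {long_clade_root!r}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, long_clade_root: Optional[str] = None) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        return cls(tree, long_clade_root=long_clade_root)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # -- identity ----------------------------------------------------------

    def _assign_ids(self) -> None:
        self._by_id: Dict[str, dendropy.Node] = {}
        k = 0
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                nid = node.taxon.label if node.taxon is not None else node.label
                if nid is None:
                    raise ValueError("unlabeled tip")
            else:
                nid = node.label if node.label else f"n{k}"
                k += 1
                node.label = nid
            node.node_id = nid
            self._by_id[nid] = node

    # -- queries -----------------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def root_id(self) -> str:
        return self.root.node_id

    @property
    def tip_labels(self) -> List[str]:
        return [leaf.node_id for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def node(self, node_id: str) -> dendropy.Node:
        return self._by_id[node_id]

    def node_ids(self) -> List[str]:
        return [n.node_id for n in self._tree.preorder_node_iter()]

    def children(self, node_id: str) -> List[str]:
        return [c.node_id for c in self._by_id[node_id].child_nodes()]

    def parent(self, node_id: str) -> Optional[str]:
        p = self._by_id[node_id].parent_node
        return p.node_id if p is not None else None

    def branch_length(self, node_id: str) -> float:
        edge = self._by_id[node_id].edge
        return float(edge.length or 0.0)

    def tips_below(self, node_id: str) -> List[str]:
        node = self._by_id[node_id]
        if node.is_leaf():
            return [node.node_id]
        return [leaf.node_id for leaf in node.leaf_iter()]

    def mrca(self, tip_ids: Sequence[str]) -> str:
        tips = list(tip_ids)
        if not tips:
            raise ValueError("mrca of an empty tip set")
        if len(tips) == 1:
            return tips[0]
        node = self._tree.mrca(taxon_labels=tips)
        return node.node_id

    def in_long_clade(self, node_id: str) -> bool:
        if self.long_clade_root is None:
            return False
        node = self._by_id[node_id]
        anc = node
        while anc is not None:
            if anc.node_id == self.long_clade_root:
                return True
            anc = anc.parent_node
        return False

    def preorder_ids(self) -> Iterable[str]:
        for node in self._tree.preorder_node_iter():
            yield node.node_id

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SpeciesTree({self.n_tips} tips, root={self.root_id!r})"
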