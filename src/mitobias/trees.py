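"""Lightweight rooted-tree container over dendropy newick parsing.

Nodes are stored as flat arrays indexed by node id (root = 0, ids assigned
in preorder), which keeps the per-site dynamic programs in
:mod:`mitobias.ancestral` simple and fast.  Multifurcations are preserved
as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass
class RootedTree:
    children: list[list[int]]          # per node id
    parent: list[int]                  # -1 for the root
    edge_length: list[float]           # branch above each node; 0.0 for the root
    name: list[str | None]             # leaf names; internal labels optional

    root: int = 0
    _postorder: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if any(l < 0 for l in self.edge_length):
            raise ValueError("negative branch length")
        if not self._postorder:
            self._postorder = self._compute_postorder()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "RootedTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        children = [[] for _ in nodes]
        parent = [-1] * len(nodes)
        length = [0.0] * len(nodes)
        names: list[str | None] = [None] * len(nodes)
        for n in nodes:
            i = index[id(n)]
            if n.parent_node is not None:
                parent[i] = index[id(n.parent_node)]
                children[parent[i]].append(i)
                length[i] = float(n.edge.length or 0.0)
            if n.taxon is not None:
                names[i] = n.taxon.label
            elif n.label:
                names[i] = n.label
        return cls(children=children, parent=parent, edge_length=length, name=names)

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted",
            preserve_underscores=True,
        )
        return cls.from_dendropy(tree)

    # -- traversal --------------------------------------------------------
    def _compute_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    @property
    def postorder(self) -> list[int]:
        return self._postorder

    @property
    def preorder(self) -> list[int]:
        return self._postorder[::-1]

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @property
    def leaves(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.is_leaf(v)]

    @property
    def leaf_names(self) -> list[str]:
        return [self.name[v] or f"leaf_{v}" for v in self.leaves]

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1
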