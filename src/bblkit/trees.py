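"""Rooted trees with named internal nodes, backed by dendropy for I/O.

The likelihood engine consumes :class:`TreeIndex`, a flat postorder-indexed
view (parent pointers, branch lengths, tip/label lookup) of a rooted tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .errors import InputError


def read_tree(source: str | Path, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree, preserving underscores and internal node labels."""
    src = str(source)
    if "(" in src and ";" in src:
        tree = dendropy.Tree.get(
            data=src, schema=schema, preserve_underscores=True, rooting="force-rooted"
        )
    else:
        path = Path(src)
        if not path.exists():
            raise InputError(f"no such tree file: {path}")
        tree = dendropy.Tree.get(
            path=str(path), schema=schema, preserve_underscores=True, rooting="force-rooted"
        )
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)


@dataclass
class TreeIndex:
    """Array view of a rooted tree in postorder.

    Attributes
    ----------
    parent : (n_nodes,) int array, -1 at the root
    lengths : (n_nodes,) float array of branch lengths above each node
    postorder : node indices, children before parents, root last
    tip_names : index -> name for leaf nodes
    labels : name -> index for every labelled node (tips and internals)
    """

    parent: np.ndarray
    lengths: np.ndarray
    children: list[list[int]]
    postorder: list[int]
    tip_names: dict[int, str]
    labels: dict[str, int]
    root: int

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, default_length: float = 0.1) -> "TreeIndex":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        tip_names: dict[int, str] = {}
        labels: dict[str, int] = {}
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
                lengths[i] = nd.edge.length if nd.edge.length is not None else default_length
                if lengths[i] < 0:
                    raise InputError(f"negative branch length {lengths[i]}")
            name = None
            if nd.taxon is not None:
                name = nd.taxon.label
            elif nd.label:
                name = nd.label
            if nd.is_leaf():
                if name is None:
                    raise InputError("unlabelled tip in tree")
                tip_names[i] = name
            if name is not None:
                if name in labels:
                    raise InputError(f"duplicate node label {name!r}")
                labels[name] = i
        root = index[id(tree.seed_node)]
        return cls(
            parent=parent,
            lengths=lengths,
            children=children,
            postorder=[index[id(nd)] for nd in nodes],
            tip_names=tip_names,
            labels=labels,
            root=root,
        )

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tips(self) -> list[int]:
        return sorted(self.tip_names)

    @property
    def tip_labels(self) -> list[str]:
        return [self.tip_names[i] for i in self.tips]

    def node(self, label: str) -> int:
        if label not in self.labels:
            raise InputError(f"node label {label!r} not in tree")
        return self.labels[label]

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder))

    def tips_below(self, node: int) -> set[str]:
        out: set[str] = set()
        stack = [node]
        while stack:
            i = stack.pop()
            if i in self.tip_names:
                out.add(self.tip_names[i])
            stack.extend(self.children[i])
        return out


def check_tip_match(tree: TreeIndex, ids: list[str]) -> None:
    """Raise unless tree tip labels are a subset of the alignment ids."""
    missing = set(tree.tip_labels) - set(ids)
    if missing:
        raise InputError(f"tree tips absent from alignment: {sorted(missing)}")
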