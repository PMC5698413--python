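"""Minimal rooted-tree structure used for genealogies and haplogroup trees.

Branch lengths are in years for simulated genealogies; edges additionally
carry a SNP mutation count (``mutations``) and, for haplogroup trees, the
names of the variants that define the edge (``variants``).  Newick text is
parsed through dendropy; mutation counts survive round trips as ``[&...]``
branch comments.
"""

from __future__ import annotations

import re
from typing import Callable, Iterator

import dendropy


class Node:
    """A tree node; ``length`` and edge annotations describe the edge above it."""

    __slots__ = ("name", "length", "parent", "children", "mutations", "variants")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.mutations: int = 0
        self.variants: list[str] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, length={self.length}, mutations={self.mutations})"


class Tree:
    """A rooted tree with named leaves."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        best = 0.0

        def walk(node: Node, depth: float) -> None:
            nonlocal best
            depth += node.length if node is not self.root else 0.0
            if node.is_leaf:
                best = max(best, depth)
            for child in node.children:
                walk(child, depth)

        walk(self.root, 0.0)
        return best

    def scale(self, factor: float) -> None:
        """Multiply every branch length in place."""
        for node in self.preorder():
            node.length *= factor

    def n_descendant_leaves(self) -> dict[Node, int]:
        counts: dict[Node, int] = {}
        for node in self.postorder():
            counts[node] = 1 if node.is_leaf else sum(counts[c] for c in node.children)
        return counts

    def find(self, name: str) -> Node:
        for node in self.preorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r}")

    # -- serialisation -----------------------------------------------------
    def to_newick(self, mutations: bool = False, lengths: bool = True) -> str:
        def render(node: Node) -> str:
            if node.children:
                inner = ",".join(render(c) for c in node.children)
                s = f"({inner})" + (node.name or "")
            else:
                s = node.name or ""
            if node is not self.root:
                if lengths:
                    s += f":{node.length:.10g}"
                if mutations:
                    s += f"[&mutations={node.mutations}]"
            return s

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )

        def convert(dnode: dendropy.Node) -> Node:
            name = None
            if dnode.taxon is not None:
                name = dnode.taxon.label
            elif dnode.label:
                name = dnode.label
            node = Node(name=name, length=dnode.edge.length or 0.0)
            for comment in dnode.comments or []:
                m = re.search(r"mutations=(\d+)", comment)
                if m:
                    node.mutations = int(m.group(1))
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.mutations = node.mutations
            new.variants = list(node.variants)
            for child in node.children:
                new.add_child(dup(child))
            return new

        return Tree(dup(self.root))
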