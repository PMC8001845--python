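"""Rooted tree structure shared by the phylogeny, reconciliation and simulation stages.

Newick parsing is delegated to dendropy; the algorithms in this package operate
on the lightweight :class:`Node` objects defined here.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional

import dendropy

__all__ = ["Node", "parse_newick", "to_newick"]


class Node:
    """A node of a rooted tree.

    Attributes
    ----------
    label:
        Node name; mandatory for leaves, optional for internal nodes (where it
        may hold bootstrap support when read from Newick).
    length:
        Length of the branch *above* this node (``None`` for the root or for
        cladogram input).
    children:
        Child nodes, in input order.
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None,
                 children: Optional[list["Node"]] = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        for child in children or []:
            self.add_child(child)

    # -- construction -------------------------------------------------------

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.remove_child(self)
        return self

    # -- predicates and traversal -------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def ancestors(self, include_self: bool = False) -> Iterator["Node"]:
        node = self if include_self else self.parent
        while node is not None:
            yield node
            node = node.parent

    def is_ancestor_of(self, other: "Node", include_self: bool = True) -> bool:
        return any(a is self for a in other.ancestors(include_self=include_self))

    def depth(self) -> int:
        """Number of edges from the root to this node."""
        return sum(1 for _ in self.ancestors())

    def find(self, label: str) -> "Node":
        for node in self.preorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    def copy(self) -> "Node":
        clone = Node(self.label, self.length)
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    # -- editing -------------------------------------------------------------

    def suppress_unary(self) -> "Node":
        """Collapse nodes with a single child; returns the (possibly new) root."""

        def collapse(node: "Node") -> "Node":
            kids = [collapse(c) for c in list(node.children)]
            node.children = []
            for kid in kids:
                node.add_child(kid)
            if len(node.children) == 1:
                child = node.children[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                child.parent = None
                return child
            return node

        root = collapse(self)
        root.parent = None
        return root

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


def _from_dendropy(dnode: dendropy.Node) -> Node:
    if dnode.taxon is not None:
        label = dnode.taxon.label
    else:
        label = dnode.label
    node = Node(label=label, length=dnode.edge.length)
    for dchild in dnode.child_nodes():
        node.add_child(_from_dendropy(dchild))
    return node


def parse_newick(text: str) -> Node:
    """Parse a Newick string into a rooted :class:`Node` tree."""
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              preserve_underscores=True,
                              suppress_internal_node_taxa=True)
    return _from_dendropy(dtree.seed_node)


def _fmt_length(x: float) -> str:
    s = f"{x:.10g}"
    return s


def to_newick(root: Node, lengths: bool = True,
              label_fn: Optional[Callable[[Node], Optional[str]]] = None) -> str:
    """Serialize a tree to a Newick string (with trailing semicolon)."""

    def fmt(node: Node) -> str:
        raw = label_fn(node) if label_fn is not None else node.label
        label = "" if raw is None else str(raw)
        if node.is_leaf:
            body = label
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")" + label
        if lengths and node.length is not None:
            body += ":" + _fmt_length(node.length)
        return body

    return fmt(root) + ";"
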