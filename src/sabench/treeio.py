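"""Rooted trees with (multi-)labeled nodes, and Newick I/O.

The central data structure is :class:`LabeledTree`: a rooted tree in which
*every* node — internal or leaf — carries an ordered set of sample names.
The set may be empty (anonymous internal nodes of inferred trees) or hold
several names (nodes produced by collapsing chains of zero-length
branches).  Branch lengths are stored exactly as given, including the
negative values that distance-based methods occasionally emit; nothing is
clamped.

Newick dialect
--------------
Multi-name nodes are serialized as plain labels with the names joined by a
delimiter (default ``"|"``), so collapsed trees survive standard Newick
parsers as ordinary labeled trees.  Trees are treated as rooted as written;
no rerooting is attempted.  A branch length absent from the input defaults
to ``0.0``; the root's branch length is meaningless and is never emitted.
A single root-only tree named ``S`` is written as ``"S;"``.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "LabeledTree",
    "parse_newick",
    "write_newick",
    "SabenchError",
    "NewickParseError",
    "ValidationError",
]

#: characters that would break the Newick encoding if they appeared in a name
NEWICK_METACHARS = set("(),:;[]'\"\t\n ")


class SabenchError(Exception):
    """Base class for all package errors."""


class NewickParseError(SabenchError):
    """Malformed Newick input."""


class ValidationError(SabenchError):
    """A tree or argument violates an invariant."""


class Node:
    """One node of a :class:`LabeledTree`.

    Parameters
    ----------
    names:
        Ordered collection of sample names carried by this node.  Empty for
        anonymous internal nodes.
    blen:
        Length of the branch connecting this node to its parent.  Stored
        as given (negative values are legal); meaningless on the root.
    day:
        Optional 1-based sampling day of the node.
    """

    __slots__ = ("names", "blen", "day", "children", "parent")

    def __init__(
        self,
        names: Optional[list[str]] = None,
        blen: float = 0.0,
        day: Optional[int] = None,
    ) -> None:
        self.names: list[str] = list(names) if names else []
        self.blen: float = float(blen)
        self.day: Optional[int] = day
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    # -- structure -------------------------------------------------------

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        """Remove this node (and its subtree) from its parent."""
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    @property
    def name(self) -> Optional[str]:
        """The single name of a singly-named node, else ``None``."""
        return self.names[0] if len(self.names) == 1 else None

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def copy(self) -> "Node":
        dup = Node(list(self.names), self.blen, self.day)
        for child in self.children:
            dup.add_child(child.copy())
        return dup

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        label = "|".join(self.names) or "<anon>"
        return f"Node({label}, blen={self.blen}, children={len(self.children)})"


class LabeledTree:
    """A rooted tree whose nodes carry sets of sample names.

    Invariants (checked by :meth:`validate`): there is exactly one root,
    the parent relation is acyclic and connected (guaranteed by
    construction), and every sample name appears at most once in the whole
    tree.
    """

    def __init__(self, root: Node) -> None:
        self.root = root
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for node in self.root.preorder():
            for name in node.names:
                if name in seen:
                    raise ValidationError(f"duplicate sample name: {name!r}")
                seen.add(name)

    # -- traversal & lookup ----------------------------------------------

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.preorder())

    def names(self) -> set[str]:
        """Set of all sample names anywhere in the tree."""
        out: set[str] = set()
        for node in self.preorder():
            out.update(node.names)
        return out

    def find(self, name: str) -> Node:
        for node in self.preorder():
            if name in node.names:
                return node
        raise KeyError(name)

    def copy(self) -> "LabeledTree":
        return LabeledTree(self.root.copy())

    # -- comparison ------------------------------------------------------

    def canonical(self, include_blen: bool = True, decimals: int = 9):
        """Hashable canonical form, insensitive to child order.

        Two trees have equal canonical forms iff they have the same shape,
        the same name set on every corresponding node, and (when
        ``include_blen``) branch lengths equal to ``decimals`` places.
        """

        def rec(node: Node, is_root: bool):
            kids = tuple(sorted(rec(c, False) for c in node.children))
            blen = -0.0 if (is_root or not include_blen) else round(node.blen, decimals)
            return (tuple(sorted(node.names)), blen, kids)

        return rec(self.root, True)

    def topology_equal(self, other: "LabeledTree", include_blen: bool = True) -> bool:
        """Equality up to reordering of children."""
        return self.canonical(include_blen) == other.canonical(include_blen)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LabeledTree({self.n_nodes} nodes, {self.n_leaves} leaves)"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _split_label(label: Optional[str], delimiter: str) -> list[str]:
    if not label:
        return []
    return [part for part in label.split(delimiter) if part]


def parse_newick(text: str, label_delimiter: str = "|") -> LabeledTree:
    """Parse a single rooted Newick tree into a :class:`LabeledTree`.

    Internal-node labels, when present, are sample names; multi-name nodes
    are encoded as names joined by ``label_delimiter``.  Branch lengths
    absent from the text default to ``0.0``.  Comments in square brackets
    are ignored.  Child order is preserved.

    Raises
    ------
    NewickParseError
        On malformed input (the message carries dendropy's line/column
        position of the offending character when available).
    ValidationError
        If a sample name occurs more than once.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error classes
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        where = f" at line {line}, column {col}" if line is not None else ""
        raise NewickParseError(f"malformed Newick{where}: {exc}") from exc

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        blen = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = Node(_split_label(label, label_delimiter), blen)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return LabeledTree(convert(dtree.seed_node))


def _format_blen(blen: float, sig_digits: int) -> str:
    return format(blen, f".{sig_digits}g")


def write_newick(
    tree: LabeledTree,
    label_delimiter: str = "|",
    sig_digits: int = 6,
) -> str:
    """Serialize a :class:`LabeledTree` to a Newick string.

    Output is deterministic: children are written in stored order,
    multi-name nodes emit their names joined by ``label_delimiter``, and
    branch lengths are printed with ``sig_digits`` significant digits.
    The root's branch length is not emitted.

    Raises
    ------
    ValidationError
        If any sample name contains the delimiter or a Newick
        metacharacter.
    """
    forbidden = NEWICK_METACHARS | {label_delimiter}
    for node in tree.preorder():
        for name in node.names:
            bad = set(name) & forbidden
            if bad:
                raise ValidationError(
                    f"sample name {name!r} contains reserved character(s) "
                    f"{sorted(bad)!r}"
                )

    def rec(node: Node, is_root: bool) -> str:
        label = label_delimiter.join(node.names)
        inner = ""
        if node.children:
            inner = "(" + ",".join(rec(c, False) for c in node.children) + ")"
        suffix = "" if is_root else f":{_format_blen(node.blen, sig_digits)}"
        return f"{inner}{label}{suffix}"

    return rec(tree.root, True) + ";"


def read_newick_file(path, label_delimiter: str = "|") -> LabeledTree:
    """Read a single Newick tree from a UTF-8 file."""
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read(), label_delimiter)


def write_newick_file(tree: LabeledTree, path, label_delimiter: str = "|") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree, label_delimiter) + "\n")
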