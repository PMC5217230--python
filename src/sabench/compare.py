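"""Similarity measures for labeled trees, and ancestral-resolution combinatorics.

Standard Robinson-Foulds distance compares leaf-labeled trees and is
useless when sequences can legitimately sit on internal nodes: a tree in
which an ancestor is placed as a leaf next to its true position is
"nearly right", yet shares almost no bipartitions with the truth.  Two
measures defined directly on *labeled* trees are used instead:

1. **Parent-child relations** — a rooted tree is described as the set of
   ordered pairs of sample names at the two ends of each branch (parent
   nearer the root); a tree is scored by the fraction of the benchmark's
   pairs it recovers.
2. **Labeled clades** — for each internal node, the set of all sample
   names strictly descendant from it (names on internal descendant nodes
   included); a tree is scored by the fraction of the benchmark's clades
   present in it.  This is the labeled-tree variant of the original
   Robinson-Foulds formulation.

The module also quantifies the ambiguity that motivates collapsing: on a
rooted bifurcating tree there are exactly 3 equally good ways to place one
ancestral sequence as a leaf next to its true node, hence ``3**k`` equally
good resolutions of a tree with ``k`` occupied internal nodes (and 15 for
a node occupied by two identical sequences — the number of rooted
bifurcating trees on 4 leaves).  :func:`resolve_random` draws one such
resolution uniformly; :func:`count_resolutions` counts them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import permutations
from typing import FrozenSet, Tuple

import numpy as np

from sabench.treeio import LabeledTree, Node, SabenchError

__all__ = [
    "RelationSet",
    "parent_child_relations",
    "parent_child_score",
    "clades",
    "clade_score",
    "resolve_random",
    "count_resolutions",
    "rooted_tree_count",
    "UndefinedScoreError",
    "UnsupportedShapeError",
]

Pair = Tuple[str, str]


class UndefinedScoreError(SabenchError):
    """The benchmark tree has no relations/clades, so a fraction is undefined."""


class UnsupportedShapeError(SabenchError):
    """Resolution operations require occupied internal nodes with exactly two children."""


@dataclass(frozen=True)
class RelationSet:
    """Parent-child description of a rooted labeled tree.

    ``pairs`` holds ordered (parent_name, child_name) pairs, one for every
    combination of names at the two ends of a branch; branches touching an
    anonymous node contribute nothing for that end.  ``colocated`` holds
    ordered pairs of distinct names sharing one (collapsed) node; these are
    kept separate because co-location is the collapsed representation of a
    zero-length branch, not a parent-child relation in its own right.
    """

    pairs: FrozenSet[Pair]
    colocated: FrozenSet[Pair] = field(default_factory=frozenset)


def parent_child_relations(tree: LabeledTree) -> RelationSet:
    """Extract the parent-child relation set of a tree.

    For every branch from node ``P`` to child ``C``, all pairs ``(p, c)``
    with ``p`` a name of ``P`` and ``c`` a name of ``C`` are emitted.
    Multi-name nodes additionally yield every ordered pair of distinct
    co-located names, reported separately in ``colocated``.
    """
    pairs: set[Pair] = set()
    colocated: set[Pair] = set()
    for node in tree.preorder():
        if len(node.names) > 1:
            colocated.update(
                (a, b) for a, b in permutations(node.names, 2)
            )
        for child in node.children:
            pairs.update((p, c) for p in node.names for c in child.names)
    return RelationSet(frozenset(pairs), frozenset(colocated))


def parent_child_score(inferred: LabeledTree, truth: LabeledTree) -> float:
    """Fraction of the benchmark's parent-child relations recovered.

    A true pair ``(p, c)`` counts as recovered when the inferred tree
    either contains the branch ``p -> c`` or places ``p`` and ``c`` on the
    same (collapsed) node — the latter being how a correctly inferred
    zero-length branch looks after collapsing.  The denominator is the
    benchmark's relation count; 1.0 iff every true branch is recovered.
    """
    r_true = parent_child_relations(truth)
    if not r_true.pairs:
        raise UndefinedScoreError("benchmark tree has no parent-child relations")
    r_inf = parent_child_relations(inferred)
    matched = sum(
        1 for pair in r_true.pairs if pair in r_inf.pairs or pair in r_inf.colocated
    )
    return matched / len(r_true.pairs)


def clades(tree: LabeledTree) -> Counter:
    """Multiset of labeled clades, one per internal node.

    A node's clade is the set of sample names on its *strict* descendants
    (its own names excluded, names on internal descendants included).
    Anonymous internal nodes still contribute their clade.  Returned as a
    :class:`collections.Counter` over frozensets because distinct internal
    nodes can carry identical clades.
    """
    out: Counter = Counter()

    def rec(node: Node) -> set[str]:
        below: set[str] = set()
        for child in node.children:
            below |= rec(child) | set(child.names)
        if node.children:
            out[frozenset(below)] += 1
        return below

    rec(tree.root)
    return out


def clade_score(inferred: LabeledTree, truth: LabeledTree) -> float:
    """Fraction of the benchmark's clades present in the inferred tree.

    Matching is exact set equality with multiset semantics: duplicate
    identical clades in the benchmark each require a distinct matching
    clade in the inferred tree.
    """
    c_true = clades(truth)
    if not c_true:
        raise UndefinedScoreError("benchmark tree has no internal nodes")
    c_inf = clades(inferred)
    matched = sum(min(n, c_inf[cl]) for cl, n in c_true.items())
    return matched / sum(c_true.values())


def rooted_tree_count(n_leaves: int) -> int:
    """Number of labeled rooted bifurcating topologies on ``n_leaves`` leaves.

    ``(2n-3)!! = 1*3*5*...*(2n-3)`` for ``n >= 2``; 1 for ``n`` in {1, 2}.
    E.g. 3 topologies for 3 leaves and 15 for 4 leaves.
    """
    if n_leaves < 1:
        raise ValueError(f"n_leaves must be >= 1, got {n_leaves}")
    count = 1
    for k in range(3, 2 * n_leaves - 2, 2):
        count *= k
    return count


def _occupied_internal(tree: LabeledTree) -> list[Node]:
    return [n for n in tree.preorder() if n.children and n.names]


def count_resolutions(tree: LabeledTree) -> int:
    """Number of equally good bifurcating leaf-only resolutions of a tree.

    Placements at distinct internal nodes are independent, so the count is
    the product over internal nodes of ``rooted_tree_count(m + c)`` where
    ``m`` is the number of occupant names at the node and ``c`` its number
    of children.  Singly occupied bifurcations contribute a factor 3, so a
    fully occupied binary tree with ``k`` internal nodes has ``3**k``
    resolutions; a doubly occupied bifurcation contributes 15.
    """
    total = 1
    for node in tree.internal_nodes():
        total *= rooted_tree_count(len(node.names) + len(node.children))
    return total


def _random_local_topology(units: list[Node], rng: np.random.Generator, extra_blen: float) -> Node:
    """Uniform random rooted bifurcating tree whose leaves are ``units``.

    Built by stepwise insertion: the j-th unit is attached on one of the
    ``2j - 3`` branches of the partial tree (the branch above the current
    root included), each choice equally likely.  Every topology arises
    from exactly one sequence of choices, so the draw is uniform over the
    ``rooted_tree_count(len(units))`` labeled topologies.  New internal
    nodes are anonymous with branch length ``extra_blen``.
    """
    unit_ids = {id(u) for u in units}

    def scaffold_edges(root: Node) -> list[Node]:
        # branches of the partial tree, in preorder, each represented by
        # the node below it; units are atomic (no descent into them)
        out = []
        stack = [root]
        while stack:
            n = stack.pop()
            if n is not root:
                out.append(n)
            if id(n) not in unit_ids:
                stack.extend(reversed(n.children))
        return out

    root = units[0]
    for unit in units[1:]:
        # attachment branches: one per scaffold node below the root, plus
        # the branch above the root, last
        edges = scaffold_edges(root)
        choice = int(rng.integers(0, len(edges) + 1))
        joint = Node([], extra_blen)
        if choice == len(edges):  # new root above the old one
            joint.add_child(root)
            joint.add_child(unit)
            root = joint
        else:
            below = edges[choice]
            parent = below.parent
            idx = parent.children.index(below)
            below.parent = None
            joint.add_child(below)
            joint.add_child(unit)
            joint.parent = parent
            parent.children[idx] = joint
    return root


def resolve_random(
    truth: LabeledTree, seed: int, extra_blen: float = 0.0
) -> LabeledTree:
    """Draw a uniform random bifurcating leaf-only resolution of ``truth``.

    Every occupant of an internal node is detached and re-attached as a
    leaf on a branch of length ``extra_blen``; for a singly occupied node
    with two children the three possible local configurations are chosen
    uniformly and independently per node, and a node with ``m`` occupants
    and ``c`` children is resolved uniformly among its
    ``rooted_tree_count(m + c)`` local topologies.  Occupied internal
    nodes are processed in preorder, each consuming draws from a single
    PCG64 stream seeded with ``seed``, so results are reproducible.

    With ``extra_blen=0`` the operation is inverted exactly by collapsing
    at cutoff 0.0.

    Raises
    ------
    UnsupportedShapeError
        If an occupied internal node does not have exactly two children.
    """
    if extra_blen < 0:
        raise ValueError("extra_blen must be >= 0")
    work = truth.copy()
    rng = np.random.default_rng(seed)
    for node in list(work.preorder()):
        if not node.children or not node.names:
            continue
        if len(node.children) != 2:
            raise UnsupportedShapeError(
                f"occupied internal node with {len(node.children)} != 2 children"
            )
        occupants = [Node([name], extra_blen, node.day) for name in node.names]
        children = list(node.children)
        for c in children:
            c.parent = None
        node.children = []
        local_root = _random_local_topology(occupants + children, rng, extra_blen)
        # the local root replaces the occupied node on its original branch
        local_root.blen = node.blen
        if node.parent is None:
            work.root = local_root
            local_root.parent = None
        else:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx] = local_root
            local_root.parent = parent
        node.parent = None
    work.validate()
    return work
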