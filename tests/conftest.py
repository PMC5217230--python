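"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own resolution
machinery: rooted-topology enumeration is done by recursive leaf
insertion over nested tuples, so counts and exhaustive resolution sets
can be checked against an implementation that shares no code with
:mod:`sabench.compare`.
"""

from __future__ import annotations

import itertools

import pytest

from sabench.design import ExperimentDesign, build_design_tree
from sabench.treeio import LabeledTree, Node


@pytest.fixture
def days2_tree() -> LabeledTree:
    return build_design_tree(ExperimentDesign(days=2))


@pytest.fixture
def days3_tree() -> LabeledTree:
    return build_design_tree(ExperimentDesign(days=3))


@pytest.fixture
def days8_tree() -> LabeledTree:
    return build_design_tree(ExperimentDesign(days=8))


# ---------------------------------------------------------------------------
# oracle: enumeration of labeled rooted bifurcating topologies
# ---------------------------------------------------------------------------


def enumerate_shapes(items):
    """All rooted bifurcating topologies over ``items``, as nested 2-tuples.

    Built by inserting one leaf at a time on every branch of every partial
    topology (including above the root); every unordered topology is
    produced exactly once, so the count is the double factorial
    1 * 3 * ... * (2n - 3).
    """
    if len(items) == 1:
        return [items[0]]
    out = []
    for shape in enumerate_shapes(items[:-1]):
        out.extend(_insert_everywhere(shape, items[-1]))
    return out


def _insert_everywhere(shape, item):
    yield (shape, item)  # above the current (sub)root
    if isinstance(shape, tuple) and len(shape) == 2:
        left, right = shape
        for new_left in _insert_everywhere(left, item):
            yield (new_left, right)
        for new_right in _insert_everywhere(right, item):
            yield (left, new_right)


def shape_to_tree(shape, subtrees: dict, extra_blen: float = 0.0) -> Node:
    """Instantiate a nested-tuple shape; atoms index into ``subtrees``
    (each subtree is copied so shapes stay independent)."""
    if not isinstance(shape, tuple):
        return subtrees[shape].copy()
    node = Node([], extra_blen)
    node.add_child(shape_to_tree(shape[0], subtrees, extra_blen))
    node.add_child(shape_to_tree(shape[1], subtrees, extra_blen))
    return node


def enumerate_resolutions(truth: LabeledTree, extra_blen: float = 0.0):
    """Exhaustively enumerate every bifurcating leaf-only resolution.

    Only feasible for trees with few occupied internal nodes (the count
    is a product of double factorials); used as the ground truth against
    which the library's counting and random sampling are checked.
    """

    def rec(node: Node) -> list[Node]:
        if not node.children:
            leaf = Node(list(node.names), node.blen)
            return [leaf]
        child_variants = [rec(c) for c in node.children]
        variants = []
        for combo in itertools.product(*child_variants):
            if not node.names:
                base = Node([], node.blen)
                for c in combo:
                    base.add_child(c.copy())
                variants.append(base)
                continue
            units = {}
            for i, name in enumerate(node.names):
                units[i] = Node([name], extra_blen)
            offset = len(node.names)
            for j, sub in enumerate(combo):
                units[offset + j] = sub
            for shape in enumerate_shapes(list(units)):
                local = shape_to_tree(shape, units, extra_blen)
                local.blen = node.blen
                variants.append(local)
        return variants

    return [LabeledTree(root) for root in rec(truth.root)]
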