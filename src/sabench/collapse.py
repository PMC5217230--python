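"""Collapsing short branches so sequences can occupy internal nodes.

Phylogenetic methods place every observed sequence at a leaf, attaching
ancestral sequences on (near-)zero-length branches next to the internal
node where they belong.  Contracting every branch at or below a length
cutoff moves those labels onto the internal nodes, recovering a tree in
which ancestors are ancestors.  Two strategies are provided:

* :func:`collapse_fixed` — contract every branch with length <= a fixed
  cutoff (the classic choice is ``0.0``, which also removes the negative
  branch lengths that distance methods occasionally produce);
* :func:`collapse_adaptive` — try the tree's own distinct branch lengths,
  in ascending order, as cutoffs until the collapsed tree has at most a
  target number of leaves (the target being the known leaf count of a
  benchmark tree).

Contraction is exhaustive: chains of short branches merge into a single
node, which is how nodes with three or more names arise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from sabench.treeio import LabeledTree, Node, ValidationError

__all__ = ["CollapseResult", "collapse_fixed", "collapse_adaptive", "NO_COLLAPSE"]

#: sentinel cutoff meaning "no collapsing was applied"
NO_COLLAPSE = -math.inf


@dataclass(frozen=True)
class CollapseResult:
    """Outcome of a collapsing operation.

    Attributes
    ----------
    tree:
        The collapsed tree (nodes may carry several names).
    cutoff_used:
        The branch-length cutoff actually applied; ``-inf`` when no
        collapsing was applied.
    n_leaves:
        Leaf count of ``tree``.
    n_collapsed_branches:
        Number of branch contractions performed.
    """

    tree: LabeledTree
    cutoff_used: float
    n_leaves: int
    n_collapsed_branches: int


def _contract_once(parent: Node, child: Node) -> None:
    """Merge ``child`` into ``parent``: names are appended, grandchildren
    are spliced in at the child's position with their own branch lengths
    unchanged."""
    idx = parent.children.index(child)
    parent.names.extend(child.names)
    for grandchild in child.children:
        grandchild.parent = parent
    parent.children[idx : idx + 1] = child.children
    child.children = []
    child.parent = None


def collapse_fixed(tree: LabeledTree, cutoff: float) -> CollapseResult:
    """Contract every branch with length <= ``cutoff``.

    "Less than or equal" is taken literally, so a cutoff of ``0.0``
    collapses zero-length *and* negative branches.  Contraction is applied
    to a fixpoint, the root is never collapsed away (its branch length is
    meaningless and ignored), and the relative order of surviving children
    is preserved.  The input tree is not modified.
    """
    work = tree.copy()
    n_contracted = 0
    # process in preorder; re-scan a node's children after each contraction
    # so chains of short branches merge into one node
    stack = [work.root]
    while stack:
        node = stack.pop()
        i = 0
        while i < len(node.children):
            child = node.children[i]
            if child.blen <= cutoff:
                _contract_once(node, child)
                n_contracted += 1
                # do not advance: spliced-in grandchildren land at i
            else:
                i += 1
        stack.extend(reversed(node.children))
    work.validate()
    return CollapseResult(
        tree=work,
        cutoff_used=cutoff,
        n_leaves=work.n_leaves,
        n_collapsed_branches=n_contracted,
    )


def collapse_adaptive(tree: LabeledTree, target_leaves: int) -> CollapseResult:
    """Collapse with the smallest cutoff reaching at most ``target_leaves``.

    Candidate cutoffs are the distinct branch lengths present in the input
    (root branch excluded), tried in ascending order; the result uses the
    smallest candidate for which :func:`collapse_fixed` leaves at most
    ``target_leaves`` leaves.  If the input already satisfies the target,
    it is returned unchanged with ``cutoff_used = -inf``.  If even the
    largest candidate leaves too many leaves, the largest is used and a
    warning is issued.
    """
    if target_leaves < 1:
        raise ValidationError(f"target_leaves must be >= 1, got {target_leaves}")
    if tree.n_leaves <= target_leaves:
        return CollapseResult(
            tree=tree.copy(),
            cutoff_used=NO_COLLAPSE,
            n_leaves=tree.n_leaves,
            n_collapsed_branches=0,
        )
    candidates = sorted(
        {node.blen for node in tree.preorder() if not node.is_root}
    )
    result = None
    for cutoff in candidates:
        result = collapse_fixed(tree, cutoff)
        if result.n_leaves <= target_leaves:
            return result
    warnings.warn(
        f"even the largest cutoff {candidates[-1]!r} leaves "
        f"{result.n_leaves} > {target_leaves} leaves",
        stacklevel=2,
    )
    return result
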