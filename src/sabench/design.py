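"""The known "ideal tree" implied by a serial-passage experiment design.

A mutation-accumulation experiment that starts from a single colony and
splits every culture into ``split`` daughters once per day defines its own
phylogeny: after ``days`` days there is one sample per node of a complete
``split``-ary tree.  Samples are named by their split path — the founder is
``S``, its daughters ``S1`` and ``S2``, their daughters ``S11, S12, S21,
S22`` and so on — so ancestry is literally the prefix relation on names.
With ``days=8`` and binary splits this yields 255 samples: 128 leaves and
127 ancestral (internal) samples.

Because sequencing does not succeed for every sample,
:func:`restrict_to_observed` projects the ideal tree onto an observed
subset of names while preserving all ancestor/descendant relations among
the observed samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from sabench.treeio import LabeledTree, Node, ValidationError

__all__ = [
    "ExperimentDesign",
    "build_design_tree",
    "sample_counts",
    "restrict_to_observed",
    "design_metadata",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameters of the serial-passage experiment.

    Attributes
    ----------
    days:
        Number of days the experiment runs (>= 1); samples are taken on
        every day, so ``days`` also counts the tree's levels.
    split:
        Number of daughter cultures per day (>= 2; the classic experiment
        splits each culture in two).
    root_name:
        Name of the founder sample (default ``"S"``).
    """

    days: int = 8
    split: int = 2
    root_name: str = "S"

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValidationError(f"days must be >= 1, got {self.days}")
        if self.split < 2:
            raise ValidationError(f"split must be >= 2, got {self.split}")
        if not self.root_name:
            raise ValidationError("root_name must be non-empty")


def build_design_tree(design: ExperimentDesign) -> LabeledTree:
    """Build the ideal tree of the experiment.

    Every node carries exactly one name; node ``X``'s children are named
    ``X1 ... X<split>``; each branch length is ``1.0`` (one day between
    consecutive samplings) and ``day`` is recorded on every node (1-based).

    For ``days=8, split=2`` the tree has 255 nodes, 128 leaves and 127
    internal nodes.
    """
    root = Node([design.root_name], blen=0.0, day=1)
    frontier = [root]
    for day in range(2, design.days + 1):
        next_frontier = []
        for node in frontier:
            stem = node.names[0]
            for i in range(1, design.split + 1):
                child = Node([f"{stem}{i}"], blen=1.0, day=day)
                node.add_child(child)
                next_frontier.append(child)
        frontier = next_frontier
    return LabeledTree(root)


def sample_counts(design: ExperimentDesign) -> list[int]:
    """Per-day sample counts: element ``d`` (1-based) equals ``split**(d-1)``.

    The sum equals the total node count of the design tree, e.g.
    ``[1, 2, 4, 8, 16, 32, 64, 128]`` summing to 255 for the 8-day binary
    experiment.
    """
    return [design.split ** (d - 1) for d in range(1, design.days + 1)]


def restrict_to_observed(tree: LabeledTree, observed: Iterable[str]) -> LabeledTree:
    """Project a singly-named tree onto an observed subset of its names.

    Nodes whose names are unobserved are removed; an unobserved internal
    node left with a single child is contracted, summing branch lengths;
    observed ancestors remain as labeled internal nodes.  The result has
    exactly ``len(observed)`` names.

    If the root itself is unobserved it is *kept as an anonymous node*
    when >= 2 observed lineages descend from it (so clade sets remain well
    defined); with a single observed lineage the chain below the root is
    contracted and the earliest observed ancestor becomes the new root.
    """
    observed = set(observed)
    known = tree.names()
    unknown = observed - known
    if unknown:
        raise ValidationError(f"unknown name(s) in observed set: {sorted(unknown)!r}")

    def rec(node: Node) -> list[Node]:
        """Return the observed-projection of ``node`` as a list of subtree
        roots to attach to the nearest observed (or kept) ancestor."""
        kept_children: list[Node] = []
        for child in node.children:
            kept_children.extend(rec(child))
        is_observed = any(n in observed for n in node.names)
        if is_observed:
            new = Node([n for n in node.names if n in observed], node.blen, node.day)
            for c in kept_children:
                new.add_child(c)
            return [new]
        # unobserved: pass surviving children upward, absorbing this
        # node's branch length into theirs
        for c in kept_children:
            c.blen += node.blen
        return kept_children

    roots = rec(tree.root)
    if not roots:
        raise ValidationError("observed set is empty")
    first_observed = any(n in observed for n in tree.root.names)
    if first_observed or len(roots) == 1:
        root = roots[0]
        root.blen = 0.0
    else:
        # unobserved true root with >= 2 observed lineages: keep it anonymous
        root = Node([], 0.0, tree.root.day)
        for c in roots:
            c.blen -= tree.root.blen  # root blen is meaningless; undo absorption
            root.add_child(c)
    return LabeledTree(root)


def design_metadata(design: ExperimentDesign) -> pd.DataFrame:
    """Tidy per-sample table (name, day, is_leaf) for the design tree."""
    tree = build_design_tree(design)
    rows = [
        {"name": node.names[0], "day": node.day, "is_leaf": node.is_leaf}
        for node in tree.preorder()
    ]
    return pd.DataFrame(rows)
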