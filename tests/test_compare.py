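"""Labeled-tree similarity measures and ancestral-resolution combinatorics."""

import itertools
from collections import Counter

import dendropy
import numpy as np
import pytest
from scipy import stats

from sabench.collapse import collapse_fixed
from sabench.compare import (
    UndefinedScoreError,
    UnsupportedShapeError,
    clade_score,
    clades,
    count_resolutions,
    parent_child_relations,
    parent_child_score,
    resolve_random,
    rooted_tree_count,
)
from sabench.design import ExperimentDesign, build_design_tree
from sabench.treeio import LabeledTree, Node, parse_newick, write_newick

from conftest import enumerate_resolutions, enumerate_shapes


# -- relation extraction ----------------------------------------------------


def test_relations_of_design_tree(days2_tree):
    rel = parent_child_relations(days2_tree)
    assert rel.pairs == {("S", "S1"), ("S", "S2")}
    assert rel.colocated == frozenset()


def test_relations_chain():
    tree = parse_newick("((S11:1)S1:1,S2:1)S;")
    rel = parent_child_relations(tree)
    assert rel.pairs == {("S", "S1"), ("S", "S2"), ("S1", "S11")}


def test_relations_multiname_expansion():
    """A node named {S1,S11} under S yields a pair for each name, plus
    both ordered co-location pairs — checked against brute-force
    enumeration over the name sets at both branch ends."""
    tree = parse_newick("((X:1)S1|S11:1,S2:1)S;")
    rel = parent_child_relations(tree)
    node_names = {"S1", "S11"}
    expected_pairs = {("S", n) for n in node_names} | {(n, "X") for n in node_names}
    expected_pairs.add(("S", "S2"))
    assert rel.pairs == expected_pairs
    assert rel.colocated == set(itertools.permutations(node_names, 2))


def test_anonymous_nodes_emit_no_relations_but_do_emit_clades():
    tree = parse_newick("((A:1,B:1):1,C:1)R;")
    rel = parent_child_relations(tree)
    # the A/B cherry hangs off an anonymous node: only (R, C) survives
    assert rel.pairs == {("R", "C")}
    assert clades(tree) == Counter(
        {frozenset({"A", "B"}): 1, frozenset({"A", "B", "C"}): 1}
    )


# -- scores -----------------------------------------------------------------


def test_self_comparison_is_perfect(days3_tree):
    assert parent_child_score(days3_tree, days3_tree) == 1.0
    assert clade_score(days3_tree, days3_tree) == 1.0


def test_parent_child_half_credit(days2_tree):
    inferred = parse_newick("(S2:1,(S1:1)S:0);")
    # inferred has (S,S1) but S2 hangs off an anonymous root: (S,S2) lost
    assert parent_child_score(inferred, days2_tree) == 0.5


def test_colocation_satisfies_true_relation(days2_tree):
    inferred = parse_newick("(S2:1)S|S1;")
    # S and S1 share a collapsed node: (S,S1) counts as recovered
    assert parent_child_score(inferred, days2_tree) == 1.0


def test_clades_of_design_trees(days2_tree, days3_tree):
    assert clades(days2_tree) == Counter({frozenset({"S1", "S2"}): 1})
    assert clades(days3_tree) == Counter(
        {
            frozenset({"S1", "S2", "S11", "S12", "S21", "S22"}): 1,
            frozenset({"S11", "S12"}): 1,
            frozenset({"S21", "S22"}): 1,
        }
    )
    assert clades(LabeledTree(Node(["S"]))) == Counter()


def test_clade_score_swapped_subtree(days3_tree):
    # swap S12 and S21 between the two cherries: only the root clade holds
    inferred = parse_newick("((S11:1,S21:1)S1:1,(S12:1,S22:1)S2:1)S;")
    assert clade_score(inferred, days3_tree) == pytest.approx(1 / 3)


def test_clade_multiset_semantics():
    """Two truth nodes with identical clades each need their own match."""
    truth = parse_newick("(((A:1,B:1):0.1)X:1,C:1)R;")
    # truth clades: {A,B} twice? no — X's clade is {A,B}, inner anon {A,B}
    truth_clades = clades(truth)
    assert truth_clades[frozenset({"A", "B"})] == 2
    inferred = parse_newick("((A:1,B:1)X:1,C:1)R;")
    # inferred contains {A,B} only once
    assert clade_score(inferred, truth) == pytest.approx(2 / 3)


def test_scores_invariant_to_child_order(days3_tree):
    flipped = parse_newick("((S22:1,S21:1)S2:1,(S12:1,S11:1)S1:1)S;")
    assert parent_child_score(flipped, days3_tree) == 1.0
    assert clade_score(flipped, days3_tree) == 1.0


def test_undefined_scores():
    single = LabeledTree(Node(["S"]))
    with pytest.raises(UndefinedScoreError):
        parent_child_score(single, single)
    with pytest.raises(UndefinedScoreError):
        clade_score(single, single)


def test_clades_match_independent_bipartition_implementation(days3_tree):
    """On leaf-labeled trees our clade sets equal the leaf sets below each
    internal node as computed by dendropy (an independent traversal)."""
    resolved = resolve_random(days3_tree, seed=21, extra_blen=0.5)
    text = write_newick(resolved)
    ours = clades(resolved)
    dtree = dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted")
    theirs = Counter(
        frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        for node in dtree.preorder_node_iter()
        if not node.is_leaf()
    )
    assert ours == theirs


# -- topology counting ------------------------------------------------------


@pytest.mark.parametrize("n,expected", [(1, 1), (2, 1), (3, 3), (4, 15), (5, 105)])
def test_rooted_tree_count_small(n, expected):
    assert rooted_tree_count(n) == expected


@pytest.mark.parametrize("n", [3, 4, 5, 6])
def test_rooted_tree_count_matches_enumeration(n):
    shapes = enumerate_shapes(list(range(n)))
    # enumeration yields each unordered topology exactly once
    assert len(shapes) == rooted_tree_count(n)
    assert rooted_tree_count(6) == 945


def test_count_resolutions(days2_tree, days8_tree):
    assert count_resolutions(days2_tree) == 3
    assert count_resolutions(days8_tree) == 3**127
    assert float(3**127) == pytest.approx(3.9e60, rel=0.01)
    # unoccupied tree: nothing to resolve
    leaf_only = resolve_random(days2_tree, seed=0)
    assert count_resolutions(leaf_only) == 1


def test_count_resolutions_two_occupants():
    # an internal node holding two identical-sequence samples plus two
    # children resolves like a rooted 4-leaf tree: 15 ways
    tree = parse_newick("(A:1,B:1)X|Y;")
    assert count_resolutions(tree) == 15


# -- random resolution ------------------------------------------------------


def test_resolve_identity_without_occupants(days2_tree):
    leaf_only = resolve_random(days2_tree, seed=0)
    again = resolve_random(leaf_only, seed=99)
    assert again.topology_equal(leaf_only)


def test_resolve_reproducible(days3_tree):
    a = resolve_random(days3_tree, seed=42)
    b = resolve_random(days3_tree, seed=42)
    assert write_newick(a) == write_newick(b)


def test_resolve_places_every_name_at_a_leaf(days3_tree):
    resolved = resolve_random(days3_tree, seed=5)
    for node in resolved.preorder():
        if node.names:
            assert node.is_leaf and len(node.names) == 1
    assert resolved.names() == days3_tree.names()
    assert resolved.n_leaves == 7


def test_resolve_rejects_non_binary_occupied_node():
    tree = parse_newick("(A:1,B:1,C:1)S;")
    with pytest.raises(UnsupportedShapeError):
        resolve_random(tree, seed=0)


def test_resolution_frequencies_uniform(days2_tree):
    """Each of the 3 single-ancestor placements appears ~1/3 of the time
    (chi-square over 3000 seeds)."""
    counts = Counter(
        resolve_random(days2_tree, seed=s).canonical(include_blen=False)
        for s in range(3000)
    )
    assert len(counts) == 3
    chi2 = stats.chisquare(list(counts.values()))
    assert chi2.pvalue > 1e-4


def test_fifteen_way_resolution_uniform():
    tree = parse_newick("(A:1,B:1)X|Y;")
    counts = Counter(
        resolve_random(tree, seed=s).canonical(include_blen=False)
        for s in range(6000)
    )
    assert len(counts) == 15
    assert stats.chisquare(list(counts.values())).pvalue > 1e-4


@pytest.mark.parametrize("days", [2, 3])
def test_exhaustive_resolutions_match_count_and_collapse_back(days):
    """Oracle equivalence on trees with <= 3 occupied internal nodes:
    independent enumeration finds exactly count_resolutions distinct
    resolutions, and every one collapses back to the truth."""
    truth = build_design_tree(ExperimentDesign(days=days))
    all_res = enumerate_resolutions(truth)
    assert len(all_res) == count_resolutions(truth)
    canon = {t.canonical(include_blen=False) for t in all_res}
    assert len(canon) == len(all_res)  # all distinct
    for resolution in all_res:
        back = collapse_fixed(resolution, 0.0).tree
        assert back.topology_equal(truth)
        assert parent_child_score(back, truth) == 1.0
        assert clade_score(back, truth) == 1.0


def test_random_resolution_lies_in_enumerated_set(days3_tree):
    universe = {
        t.canonical(include_blen=False) for t in enumerate_resolutions(days3_tree)
    }
    for seed in range(40):
        drawn = resolve_random(days3_tree, seed=seed)
        assert drawn.canonical(include_blen=False) in universe
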