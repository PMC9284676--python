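"""Neighbor-Joining, split extraction, consensus networks, RF distance."""

import itertools

import dendropy
import numpy as np
import pytest

from repeatome_kit import (
    consensus_network,
    neighbor_joining,
    parse_newick,
    robinson_foulds,
    serialize_newick,
    simulate_tree,
    tree_splits,
)
from repeatome_kit.distance import DistanceMatrix


def dm(labels, matrix):
    return DistanceMatrix(list(labels), np.asarray(matrix, float), "euclidean")


def patristic(tree):
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in labels}
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return labels, m


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        t = neighbor_joining(dm("ABC", [[0, 2, 3], [2, 0, 4], [3, 4, 0]]))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_additive_quartet_recovered_exactly(self):
        # matrix from ((A:1,B:2):1,(C:3,D:4))
        m = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        t = neighbor_joining(dm("ABCD", m))
        splits = tree_splits(t).nontrivial()
        assert len(splits) == 1
        (side,) = splits
        assert side == frozenset({"C", "D"})  # the AB|CD split
        weight, _ = splits[side]
        assert weight == pytest.approx(1.0)
        labels, back = patristic(t)
        assert np.allclose(back, np.asarray(m, float))

    @pytest.mark.parametrize("seed", range(5))
    def test_ultrametric_five_taxon_topology_recovered(self, seed):
        gen = simulate_tree(5, seed)
        labels, m = patristic(gen)
        nj = neighbor_joining(dm(labels, m))
        assert robinson_foulds(gen, nj) == 0

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(dm("AB", [[0, 1], [1, 0]]))

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN|finite"):
            neighbor_joining(
                dm("ABC", [[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
            )

    def test_no_negative_branch_lengths(self):
        # near-degenerate matrix that produces negative raw estimates
        m = [[0, 0.1, 2.0, 2.0], [0.1, 0, 2.0, 2.1], [2.0, 2.0, 0, 0.1], [2.0, 2.1, 0.1, 0]]
        t = neighbor_joining(dm("ABCD", m))
        for e in t.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scikit_bio_on_random_additive_matrices(self, seed):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        gen = simulate_tree(6, 100 + seed)
        labels, m = patristic(gen)
        ours = neighbor_joining(dm(labels, m))
        theirs = parse_newick(str(sk_nj(SkDM(m, ids=labels))))
        assert robinson_foulds(ours, theirs) == 0


class TestTreeSplits:
    def test_quartet_single_nontrivial_split(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert set(tree_splits(t).nontrivial()) == {frozenset({"C", "D"})}

    def test_star_tree_has_no_nontrivial_splits(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        assert tree_splits(t).nontrivial() == {}

    def test_caterpillar_split_count_is_n_minus_3(self):
        t = parse_newick("((((A:1,B:1):1,C:1):1,D:1):1,E:1);")
        assert len(tree_splits(t).nontrivial()) == 2

    def test_degree_two_root_edges_merge_into_one_split(self):
        rooted = parse_newick("((A:1,B:1):0.5,(C:1,D:1):0.7);")
        splits = tree_splits(rooted).nontrivial()
        (weight, _support) = splits[frozenset({"C", "D"})]
        assert weight == pytest.approx(1.2)  # 0.5 + 0.7 across the root


class TestConsensusNetwork:
    quartets = {
        "AB|CD": "((A:1,B:1):1,(C:1,D:1):1);",
        "AC|BD": "((A:1,C:1):1,(B:1,D:1):1);",
    }

    def test_identical_trees_reproduce_their_splits(self):
        trees = [parse_newick(self.quartets["AB|CD"]) for _ in range(4)]
        net = consensus_network(trees, threshold=0.25)
        non = net.nontrivial()
        assert set(non) == {frozenset({"C", "D"})}
        assert non[frozenset({"C", "D"})][1] == 1.0

    def test_low_threshold_keeps_conflicting_splits(self):
        trees = [
            parse_newick(self.quartets["AB|CD"]),
            parse_newick(self.quartets["AB|CD"]),
            parse_newick(self.quartets["AC|BD"]),
        ]
        non = consensus_network(trees, threshold=0.25).nontrivial()
        supports = {s: round(sup, 3) for s, (_, sup) in non.items()}
        assert supports == {
            frozenset({"C", "D"}): 0.667,
            frozenset({"B", "D"}): 0.333,
        }

    def test_majority_threshold_drops_minority_split(self):
        trees = [
            parse_newick(self.quartets["AB|CD"]),
            parse_newick(self.quartets["AB|CD"]),
            parse_newick(self.quartets["AC|BD"]),
        ]
        non = consensus_network(trees, threshold=0.5).nontrivial()
        assert set(non) == {frozenset({"C", "D"})}

    def test_majority_rule_split_set_is_compatible(self):
        trees = [simulate_tree(6, s) for s in range(7)]
        non = consensus_network(trees, threshold=0.5).nontrivial()
        for s1, s2 in itertools.combinations(non, 2):
            taxa = set().union(*[set(t) for t in non]) | set(trees[0].taxon_namespace.labels())
            taxa = {lf.taxon.label for lf in trees[0].leaf_node_iter()}
            a, b = set(s1), set(s2)
            assert (
                not (a & b) or a <= b or b <= a or (a | b) == taxa
            ), "incompatible splits above majority threshold"

    def test_mismatched_tip_sets_named(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError, match="E"):
            consensus_network([t1, t2])


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = simulate_tree(8, 1)
        assert robinson_foulds(t, t) == 0

    def test_conflicting_quartets(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(t1, t2) == 2

    def test_single_nni_move_distance_two(self):
        t1 = parse_newick("((A:1,B:1):1,((C:1,D:1):1,((E:1,F:1):1,(G:1,H:1):1):1):1);")
        t2 = parse_newick("((A:1,B:1):1,((E:1,F:1):1,((C:1,D:1):1,(G:1,H:1):1):1):1);")
        assert robinson_foulds(t1, t2) == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_dendropy(self, seed):
        t1 = simulate_tree(8, seed)
        t2 = simulate_tree(8, 50 + seed)
        ns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=serialize_newick(t1), schema="newick", taxon_namespace=ns)
        d2 = dendropy.Tree.get(data=serialize_newick(t2), schema="newick", taxon_namespace=ns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert robinson_foulds(t1, t2) == expected

    def test_mismatched_tips_rejected(self):
        t1 = parse_newick("((A:1,B:1):1,C:1);")
        t2 = parse_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError, match="C.*D|D.*C"):
            robinson_foulds(t1, t2)
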