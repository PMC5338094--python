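import math

import dendropy
import numpy as np
import pytest

from dupfam.io_formats import MultipleAlignment, SequenceRecord
from dupfam.phylo import (
    ConcertedStat,
    DistanceMatrix,
    DistanceSaturationError,
    bootstrap_support,
    concerted_stat,
    distance_matrix,
    k2p_distance,
    nj_tree,
    p_distance_matrix,
    tree_bipartitions,
)
from dupfam.simulate import FamilySimConfig, random_additive_matrix, simulate_gene_family

from oracles import best_topology_splits


def _tree_path_lengths(tree):
    """Leaf-to-leaf patristic distances from a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.distance(taxa[i], taxa[j])
    return [t.label for t in taxa], D


class TestK2P:
    def test_identical_sequences(self):
        res = k2p_distance("ACGTACGT", "ACGTACGT")
        assert res.d == 0.0 and res.P == 0.0 and res.Q == 0.0
        assert res.sites_used == 8

    def test_transitions_only_closed_form(self):
        # 100 sites, 10 A->G transitions: d = -1/2 ln(0.8)
        s1 = "A" * 100
        s2 = "G" * 10 + "A" * 90
        res = k2p_distance(s1, s2)
        assert res.P == pytest.approx(0.10)
        assert res.Q == 0.0
        assert round(res.d, 6) == 0.111572

    def test_transversions_enter_q_not_p(self):
        s1 = "A" * 100
        s2 = "C" * 10 + "A" * 90
        res = k2p_distance(s1, s2)
        assert res.P == 0.0
        assert res.Q == pytest.approx(0.10)

    def test_pairwise_deletion_excludes_gapped_site(self):
        # sequences differ only at a site that is gapped in one of them
        s1 = "ACGTACGTA-"
        s2 = "ACGTACGTAG"
        res = k2p_distance(s1, s2)
        assert res.d == 0.0
        assert res.sites_used == 9

    def test_ambiguity_codes_excluded(self):
        res = k2p_distance("ACGTN", "ACGTA")
        assert res.sites_used == 4
        assert res.d == 0.0

    def test_saturation_raises(self):
        with pytest.raises(DistanceSaturationError):
            k2p_distance("A" * 10, "G" * 10)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance("ACGT", "ACG")

    def test_hand_counted_toy(self):
        # 10 sites: pos0 A->G (transition), pos5 C->T (transition)
        s1 = "ACGTACGTAC"
        s2 = "GCGTATGTAC"
        res = k2p_distance(s1, s2)
        P, Q = 2 / 10, 0.0
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert res.d == pytest.approx(expected)
        assert res.sites_used == 10

    def test_k2p_at_least_p_distance(self, family_alignment):
        """The multiple-hit correction can only inflate the raw mismatch
        fraction."""
        dm = distance_matrix(family_alignment)
        pm = p_distance_matrix(family_alignment)
        assert (dm.d + 1e-12 >= pm.d).all()


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        records = [SequenceRecord(f"s{i}", "ACGTACGT") for i in range(3)]
        aln = MultipleAlignment(records, ["a", "a", "b"], ["p1", "p2", "p1"])
        dm = distance_matrix(aln)
        assert not dm.d.any()

    def test_symmetric_on_simulated_alignment(self, family_alignment):
        dm = distance_matrix(family_alignment)
        assert np.array_equal(dm.d, dm.d.T)
        assert np.array_equal(dm.sites_used, dm.sites_used.T)

    def test_matches_pairwise_k2p(self, family_alignment):
        dm = distance_matrix(family_alignment)
        s0 = family_alignment.records[0].sequence
        s1 = family_alignment.records[1].sequence
        assert dm.d[0, 1] == pytest.approx(k2p_distance(s0, s1).d)

    def test_needs_three_sequences(self):
        records = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")]
        aln = MultipleAlignment(records, ["x", "y"], ["p", "p"])
        with pytest.raises(ValueError):
            distance_matrix(aln)


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:4))
        labels = list("ABCD")
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(labels, D, np.ones((4, 4), dtype=int)))
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        got_labels, got = _tree_path_lengths(tree)
        assert got_labels == labels
        assert np.allclose(got, D, atol=1e-9)
        # the internal branch separating AB from CD has length 1
        internal = [
            n.edge.length
            for n in tree.preorder_node_iter()
            if n.parent_node is not None and not n.is_leaf()
        ]
        assert internal == pytest.approx([1.0])

    def test_three_taxa_three_point_formulas(self):
        labels = list("ABC")
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(labels, D, np.ones((3, 3), dtype=int)))
        _, got = _tree_path_lengths(tree)
        assert np.allclose(got, D, atol=1e-12)

    @pytest.mark.parametrize("n_leaves", [5, 6])
    def test_recovers_topology_verified_by_enumeration(self, n_leaves):
        for seed in range(5):
            labels, D, true_splits = random_additive_matrix(n_leaves, seed=seed)
            tree = nj_tree(DistanceMatrix(labels, D, np.ones_like(D, dtype=int)))
            nj_splits = tree_bipartitions(tree)
            assert nj_splits == true_splits
            assert nj_splits == best_topology_splits(labels, D)

    def test_exact_on_random_additive_matrices(self):
        for seed in range(30):
            n = 4 + seed % 9  # 4..12 leaves
            labels, D, true_splits = random_additive_matrix(n, seed=100 + seed)
            tree = nj_tree(DistanceMatrix(labels, D, np.ones_like(D, dtype=int)))
            assert tree_bipartitions(tree) == true_splits
            got_labels, got = _tree_path_lengths(tree)
            assert got_labels == labels
            assert np.abs(got - D).max() < 1e-9

    def test_label_order_invariance(self):
        labels, D, _ = random_additive_matrix(8, seed=7)
        tree = nj_tree(DistanceMatrix(labels, D, np.ones_like(D, dtype=int)))
        perm = np.random.default_rng(1).permutation(len(labels))
        labels2 = [labels[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        tree2 = nj_tree(DistanceMatrix(labels2, D2, np.ones_like(D2, dtype=int)))
        assert tree_bipartitions(tree) == tree_bipartitions(tree2)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], dtype=float)
        with pytest.raises(ValueError):
            DistanceMatrix(list("ABC"), D, np.ones((3, 3), dtype=int))


class TestBootstrap:
    def test_identical_sequences_no_resolved_supports(self):
        records = [SequenceRecord(f"s{i}", "ACGTACGTAC") for i in range(5)]
        aln = MultipleAlignment(records, ["a"] * 3 + ["b"] * 2, [f"p{i}" for i in range(5)])
        tree = bootstrap_support(aln, n_replicates=20, seed=0)
        labeled = [n.label for n in tree.preorder_node_iter() if not n.is_leaf() and n.label]
        assert labeled == []

    def test_same_seed_identical_supports(self, family_alignment):
        a = bootstrap_support(family_alignment, n_replicates=100, seed=3)
        b = bootstrap_support(family_alignment, n_replicates=100, seed=3)
        assert a.as_string(schema="newick") == b.as_string(schema="newick")

    def test_long_internal_branch_strongly_supported(self):
        """A deep duplication split (long internal branch) should get near
        total bootstrap support."""
        strong = 0
        for seed in range(10):
            aln = simulate_gene_family(
                FamilySimConfig(
                    n_paralogs=2,
                    root_length=1000,
                    speciation_depth=0.02,
                    duplication_depth=0.4,
                    seed=seed,
                )
            )
            tree = bootstrap_support(aln, n_replicates=100, seed=seed)
            supports = [
                int(n.label)
                for n in tree.preorder_node_iter()
                if not n.is_leaf() and n.label
            ]
            if supports and min(supports) >= 95:
                strong += 1
        assert strong >= 9

    def test_supports_are_percentages(self, family_alignment):
        tree = bootstrap_support(family_alignment, n_replicates=50, seed=1)
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.label:
                assert 0 <= int(node.label) <= 100


class TestConcertedStat:
    def _dm_two_by_two(self, within, between):
        labels = ["spA_P1", "spA_P2", "spB_P1", "spB_P2"]
        D = np.full((4, 4), between)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = within
        D[2, 3] = D[3, 2] = within
        return DistanceMatrix(labels, D, np.ones((4, 4), dtype=int))

    def test_hand_arithmetic(self):
        dm = self._dm_two_by_two(0.01, 0.05)
        stat = concerted_stat(dm, ["spA", "spA", "spB", "spB"])
        assert stat.W == pytest.approx(0.01)
        assert stat.B == pytest.approx(0.05)
        assert stat.ratio == pytest.approx(0.2)
        assert stat.within_species_monophyly == {"spA": True, "spB": True}

    def test_all_distances_equal_gives_ratio_one(self):
        dm = self._dm_two_by_two(0.05, 0.05)
        stat = concerted_stat(dm, ["spA", "spA", "spB", "spB"])
        assert stat.ratio == pytest.approx(1.0)

    def test_single_copy_species_contributes_no_within_pairs(self):
        labels = ["spA_P1", "spB_P1", "spB_P2"]
        D = np.array([[0, 0.05, 0.05], [0.05, 0, 0.01], [0.05, 0.01, 0]])
        dm = DistanceMatrix(labels, D, np.ones((3, 3), dtype=int))
        stat = concerted_stat(dm, ["spA", "spB", "spB"])
        assert stat.W == pytest.approx(0.01)

    def test_all_species_single_copy_rejected(self):
        labels = ["spA_P1", "spB_P1", "spC_P1"]
        D = np.array([[0, 0.05, 0.05], [0.05, 0, 0.01], [0.05, 0.01, 0]])
        dm = DistanceMatrix(labels, D, np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="within"):
            concerted_stat(dm, ["spA", "spB", "spC"])

    def test_detects_conversion_on_simulated_family(self):
        aln = simulate_gene_family(FamilySimConfig(gene_conversion_rate=10.0, seed=5))
        stat = concerted_stat(distance_matrix(aln), aln.species, aln.paralogs)
        assert stat.ratio < 1
        assert all(stat.within_species_monophyly.values())

    def test_null_gives_orthologous_clustering(self):
        aln = simulate_gene_family(FamilySimConfig(seed=5))
        stat = concerted_stat(distance_matrix(aln), aln.species, aln.paralogs)
        assert stat.ratio > 1
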