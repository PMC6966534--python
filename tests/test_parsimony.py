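"""Sankoff migration parsimony, comigrations, and polytomy resolution."""

import itertools

import numpy as np
import pytest

from conftest import brute_force_pmh, random_tree, tree_from_nested

from tumorbiogeo.parsimony import (
    count_comigrations,
    enumerate_optimal_labelings,
    extract_migration_graph,
    infer_pmh,
    resolve_polytomies_pmh_tr,
    sankoff_min_migrations,
)
from tumorbiogeo.phylo import ClonePhylogeny


class TestSankoff:
    def test_cherry_forced_single_migration(self):
        tree = tree_from_nested(("A", "B"))
        mu, _ = sankoff_min_migrations(tree, {"A": "P", "B": "M1"}, "P")
        assert mu == 1

    def test_two_cherries_brute_force_value(self):
        tree = tree_from_nested((("A", "B"), ("C", "D")))
        labels = {"A": "P", "B": "M1", "C": "M1", "D": "M1"}
        # exhaustive check over all internal labelings
        sites = ("M1", "P")
        expected = brute_force_pmh(tree, labels, sites, "P")[0]
        mu, _ = sankoff_min_migrations(tree, labels, "P")
        assert mu == expected == 2

    def test_uniform_labels_no_migrations(self):
        tree = tree_from_nested((("A", "B"), "C"))
        mu, _ = sankoff_min_migrations(tree, dict.fromkeys("ABC", "P"), "P")
        assert mu == 0

    def test_unconstrained_never_worse_than_constrained(self, rng):
        for _ in range(25):
            tree = random_tree(rng, int(rng.integers(3, 8)), polytomy_prob=0.3)
            sites = ("M1", "M2", "P")
            labels = {l: sites[int(rng.integers(3))] for l in tree.leaves}
            free, _ = sankoff_min_migrations(tree, labels, None, sites)
            conP, _ = sankoff_min_migrations(tree, labels, "P", sites)
            assert free <= conP

    def test_missing_leaf_label_rejected(self):
        tree = tree_from_nested(("A", "B"))
        with pytest.raises(ValueError, match="label"):
            sankoff_min_migrations(tree, {"A": "P"}, "P")

    def test_constraint_outside_alphabet_rejected(self):
        tree = tree_from_nested(("A", "B"))
        with pytest.raises(ValueError, match="alphabet"):
            sankoff_min_migrations(tree, {"A": "P", "B": "P"}, "M9")


class TestEnumeration:
    def test_unconstrained_cherry_has_two_optima(self):
        tree = tree_from_nested(("A", "B"))
        _, tables = sankoff_min_migrations(tree, {"A": "P", "B": "M1"}, None)
        labs, truncated = enumerate_optimal_labelings(tables)
        assert len(labs) == 2 and not truncated
        roots = {lab[tree.root] for lab in labs}
        assert roots == {"P", "M1"}

    def test_constrained_cherry_has_one_optimum(self):
        tree = tree_from_nested(("A", "B"))
        _, tables = sankoff_min_migrations(tree, {"A": "P", "B": "M1"}, "P")
        labs, truncated = enumerate_optimal_labelings(tables)
        assert len(labs) == 1 and not truncated

    def test_cap_sets_truncation_flag(self):
        tree = tree_from_nested(("A", "B"))
        _, tables = sankoff_min_migrations(tree, {"A": "P", "B": "M1"}, None)
        labs, truncated = enumerate_optimal_labelings(tables, cap=1)
        assert len(labs) == 1 and truncated

    def test_deterministic_order(self):
        tree = tree_from_nested((("A", "B"), "C"))
        labels = {"A": "P", "B": "M1", "C": "M1"}
        _, tables = sankoff_min_migrations(tree, labels, None)
        first = enumerate_optimal_labelings(tables)[0]
        second = enumerate_optimal_labelings(tables)[0]
        assert first == second


class TestComigrations:
    def setup_method(self):
        # root with two cherry children: migrations can sit on siblings
        self.tree = tree_from_nested((("A", "B"), ("C", "D")), prefix="n")
        # n0 = root, n1 = (A,B), n2 = (C,D)

    def test_sibling_migrations_are_one_comigration(self):
        lab = {"n0": "P", "n1": "P", "n2": "P",
               "A": "M1", "B": "P", "C": "M1", "D": "P"}
        assert count_comigrations(self.tree, lab) == 1

    def test_nested_migrations_cannot_be_simultaneous(self):
        tree = tree_from_nested((("A", ("B", "C")), "D"), prefix="m")
        # m0=root, m1=(A,(B,C)), m2=(B,C)
        lab = {"m0": "P", "m1": "M1", "m2": "P", "A": "M1", "B": "M1", "C": "P",
               "D": "P"}
        # P->M1 edges m0->m1 and m2->B lie on one root-to-leaf path, so the
        # pair (P, M1) contributes a chain of length 2; the intervening
        # return M1->P (m1->m2) adds one more comigration
        assert count_comigrations(tree, lab) == 3

    def test_distinct_pairs_count_separately(self):
        lab = {"n0": "P", "n1": "P", "n2": "P",
               "A": "M1", "B": "P", "C": "M2", "D": "P"}
        assert count_comigrations(self.tree, lab) == 2


class TestMigrationGraphExtraction:
    def test_single_discordant_edge(self):
        tree = tree_from_nested(("A", "B"), prefix="x")
        g = extract_migration_graph(tree, {"x0": "P", "A": "P", "B": "M1"})
        assert dict(g.edges) == {("P", "M1"): 1}

    def test_concordant_labeling_empty_graph(self):
        tree = tree_from_nested(("A", "B"), prefix="x")
        g = extract_migration_graph(tree, dict.fromkeys(["x0", "A", "B"], "P"))
        assert g.n_migrations == 0

    def test_chain_of_sites_along_path(self):
        tree = tree_from_nested((("A", "B"), "C"), prefix="x")
        # x0 root, x1 = (A,B)
        g = extract_migration_graph(
            tree, {"x0": "P", "x1": "M1", "A": "M2", "B": "M1", "C": "P"}
        )
        assert dict(g.edges) == {("P", "M1"): 1, ("M1", "M2"): 1}


class TestInferPmh:
    def test_lexicographic_optimality_on_random_trees(self, rng):
        sites = ("M1", "M2", "P")
        for _ in range(30):
            tree = random_tree(rng, int(rng.integers(3, 6)), polytomy_prob=0.25)
            labels = {l: sites[int(rng.integers(3))] for l in tree.leaves}
            hist = infer_pmh(tree, labels, "P", sites=sites)
            assert hist.counts == brute_force_pmh(tree, labels, sites, "P")

    def test_single_site_dataset_empty_graph(self):
        tree = tree_from_nested((("A", "B"), "C"))
        hist = infer_pmh(tree, dict.fromkeys("ABC", "P"), "P")
        assert hist.counts == (0, 0, 0)
        assert hist.graph.n_migrations == 0

    def test_counts_consistent_with_graph(self, rng):
        tree = random_tree(rng, 6)
        sites = ("M1", "M2", "P")
        labels = {l: sites[int(rng.integers(3))] for l in tree.leaves}
        hist = infer_pmh(tree, labels, "P", sites=sites)
        assert hist.migrations == hist.graph.n_migrations
        assert hist.sources == hist.graph.n_sources
        assert hist.comigrations <= hist.migrations


class TestPmhTr:
    def test_binary_tree_unchanged(self):
        tree = tree_from_nested((("A", "B"), ("C", "D")))
        labels = {"A": "P", "B": "M1", "C": "M1", "D": "P"}
        resolved, hist = resolve_polytomies_pmh_tr(tree, labels, "P")
        assert resolved.children == tree.children
        assert hist.counts == infer_pmh(tree, labels, "P").counts

    def test_star_groups_same_site_leaves(self):
        tree = ClonePhylogeny("r", {"r": ["A", "B", "C"]})
        labels = {"A": "P", "B": "M1", "C": "M1"}
        resolved, hist = resolve_polytomies_pmh_tr(tree, labels, "P")
        assert resolved.is_binary()
        assert hist.migrations == 1
        # the two M1 leaves must form a clade
        assert frozenset({"B", "C"}) in resolved.leaf_clades()

    def test_star_uniform_site_zero_migrations(self):
        tree = ClonePhylogeny("r", {"r": list("ABCD")})
        resolved, hist = resolve_polytomies_pmh_tr(
            tree, dict.fromkeys("ABCD", "P"), "P"
        )
        assert resolved.is_binary()
        assert hist.migrations == 0

    def test_refinement_preserves_input_clades(self, rng):
        for _ in range(10):
            tree = random_tree(rng, 6, polytomy_prob=0.6)
            sites = ("M1", "M2", "P")
            labels = {l: sites[int(rng.integers(3))] for l in tree.leaves}
            resolved, hist = resolve_polytomies_pmh_tr(tree, labels, "P", sites=sites)
            assert resolved.is_binary()
            assert tree.leaf_clades() <= resolved.leaf_clades()
            mu_con = infer_pmh(tree, labels, "P", sites=sites).migrations
            assert hist.migrations <= mu_con

    def test_large_polytomy_uses_greedy_resolution(self):
        leaves = [f"L{i}" for i in range(8)]
        tree = ClonePhylogeny("r", {"r": leaves})
        labels = {l: ("P" if i % 2 else "M1") for i, l in enumerate(leaves)}
        resolved, hist = resolve_polytomies_pmh_tr(tree, labels, "P")
        assert resolved.is_binary()
        assert hist.migrations == 1

    def test_large_polytomy_without_local_search_rejected(self):
        tree = ClonePhylogeny("r", {"r": [f"L{i}" for i in range(8)]})
        labels = dict.fromkeys((f"L{i}" for i in range(8)), "P")
        with pytest.raises(ValueError, match="polytomy"):
            resolve_polytomies_pmh_tr(tree, labels, "P", local_search=False)
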