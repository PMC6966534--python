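"""Bayesian ancestral-site inference: pruning, MCMC, event annotation."""

import numpy as np
import pytest

from conftest import brute_force_posteriors, random_tree, tree_from_nested

from tumorbiogeo.bayes import (
    AncestralPosterior,
    BiogeoEvent,
    McmcConfig,
    MkModel,
    annotate_events,
    infer_bbm,
    marginal_posteriors,
    mcmc_sample,
)
from tumorbiogeo.phylo import ClonePhylogeny, GERMLINE
from tumorbiogeo.simulate import SimConfig, simulate_dataset


class TestMkModel:
    def test_rows_sum_to_one(self):
        for k in (2, 5, 11):
            p = MkModel(k).transition_matrix(3.0)
            assert np.allclose(p.sum(axis=1), 1.0)
            assert np.all(p >= 0)

    def test_symmetric_equal_rates(self):
        p = MkModel(4).transition_matrix(2.0)
        assert np.allclose(p, p.T)
        off = p[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_too_few_states_rejected(self):
        with pytest.raises(ValueError):
            MkModel(1)


class TestMarginalPosteriors:
    def test_symmetric_cherry_root_is_uniform(self):
        tree = tree_from_nested(("A", "B"), prefix="x")
        tree.branch_lengths.update({"A": 2.0, "B": 2.0})
        post = marginal_posteriors(
            tree, {"A": "P", "B": "M1"}, MkModel(2), ("M1", "P")
        )
        assert np.allclose(post.probs["x0"], [0.5, 0.5])

    def test_long_branches_approach_uniform(self):
        tree = tree_from_nested(("A", "B"), prefix="x")
        tree.branch_lengths.update({"A": 1e6, "B": 1e6})
        post = marginal_posteriors(
            tree, {"A": "P", "B": "P"}, MkModel(3), ("M1", "M2", "P")
        )
        assert np.allclose(post.probs["x0"], 1 / 3, atol=1e-6)

    def test_matches_enumeration_oracle(self, rng):
        sites = ("M1", "M2", "P")
        model = MkModel(3)
        for _ in range(10):
            tree = random_tree(rng, int(rng.integers(3, 7)))
            labels = {l: sites[int(rng.integers(3))] for l in tree.leaves}
            post = marginal_posteriors(tree, labels, model, sites)
            oracle = brute_force_posteriors(tree, labels, model, sites)
            for v in tree.nodes:
                assert np.allclose(post.probs[v], oracle[v], atol=1e-9)

    def test_normalization_everywhere(self, rng):
        tree = random_tree(rng, 8)
        sites = ("M1", "M2", "P")
        labels = {l: sites[int(rng.integers(3))] for l in tree.leaves}
        post = marginal_posteriors(tree, labels, MkModel(3), sites)
        for v in tree.nodes:
            assert abs(post.probs[v].sum() - 1.0) < 1e-9
            assert np.all(post.probs[v] >= 0)

    def test_site_permutation_symmetry(self, rng):
        # relabeling the sites permutes the posteriors identically
        tree = random_tree(rng, 6)
        sites = ("M1", "M2", "P")
        labels = {l: sites[int(rng.integers(3))] for l in tree.leaves}
        model = MkModel(3)
        post = marginal_posteriors(tree, labels, model, sites)
        perm = {"M1": "M2", "M2": "P", "P": "M1"}
        labels2 = {l: perm[s] for l, s in labels.items()}
        post2 = marginal_posteriors(tree, labels2, model, sites)
        for v in tree.nodes:
            for i, s in enumerate(sites):
                j = sites.index(perm[s])
                assert post.probs[v][i] == pytest.approx(post2.probs[v][j], abs=1e-12)

    def test_unlabeled_leaf_rejected(self):
        tree = tree_from_nested(("A", "B"))
        with pytest.raises(ValueError, match="label"):
            marginal_posteriors(tree, {"A": "P"}, MkModel(2), ("M1", "P"))


class TestMcmc:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            McmcConfig(chains=0)
        with pytest.raises(ValueError):
            McmcConfig(generations=1000, sample_interval=10, burnin_samples=100)

    def test_symmetric_cherry_frequencies(self):
        tree = tree_from_nested(("A", "B"), prefix="x")
        tree.branch_lengths.update({"A": 2.0, "B": 2.0})
        mc = McmcConfig(chains=2, generations=40_000, sample_interval=1,
                        burnin_samples=500, seed=3)
        est, diag = mcmc_sample(
            tree, {"A": "P", "B": "M1"}, MkModel(2), mc, ("M1", "P")
        )
        # exact root posterior is (0.5, 0.5); allow 3 MC standard errors
        # of an independent-sample binomial (correlated draws are wider,
        # hence the generous multiplier)
        n = diag["pooled_samples"]
        tol = 10 * 0.5 / np.sqrt(n)
        assert abs(est.probs["x0"][0] - 0.5) < max(tol, 0.02)

    def test_converges_to_pruning(self, rng):
        sites = ("M1", "M2", "P")
        tree = random_tree(rng, 5)
        labels = {l: sites[int(rng.integers(3))] for l in tree.leaves}
        model = MkModel(3)
        exact = marginal_posteriors(tree, labels, model, sites)
        mc = McmcConfig(chains=2, generations=100_000, sample_interval=1,
                        burnin_samples=1000, seed=11)
        est, _ = mcmc_sample(tree, labels, model, mc, sites)
        for v in tree.nodes:
            if not tree.is_leaf(v):
                assert np.abs(est.probs[v] - exact.probs[v]).max() < 0.03

    def test_seed_reproducible_and_seed_sensitive(self):
        tree = tree_from_nested((("A", "B"), "C"), prefix="x")
        labels = {"A": "P", "B": "M1", "C": "M1"}
        model = MkModel(2)
        mc1 = McmcConfig(chains=1, generations=5000, sample_interval=1,
                         burnin_samples=100, seed=1)
        a, _ = mcmc_sample(tree, labels, model, mc1, ("M1", "P"))
        b, _ = mcmc_sample(tree, labels, model, mc1, ("M1", "P"))
        assert all(np.array_equal(a.probs[v], b.probs[v]) for v in a.probs)
        mc2 = McmcConfig(chains=1, generations=5000, sample_interval=1,
                         burnin_samples=100, seed=2)
        c, _ = mcmc_sample(tree, labels, model, mc2, ("M1", "P"))
        assert any(not np.array_equal(a.probs[v], c.probs[v]) for v in a.probs)


class TestInferBbm:
    def test_uniform_leaves_empty_graph(self):
        tree = tree_from_nested((("A", "B"), "C"), prefix="x")
        labels = dict.fromkeys("ABC", "P")
        hist, post = infer_bbm(tree, labels, MkModel(2), sites=("M1", "P"))
        assert hist.graph.n_migrations == 0
        for v in tree.nodes:
            assert post.probs[v][1] > 0.9  # concentrated on P

    def test_root_map_is_primary_with_germline_outgroup(self, rng):
        for scenario in ("mS", "pR"):
            ds = simulate_dataset(
                SimConfig(scenario=scenario, tumor_class="m5", seed=77)
            )
            labels = dict(ds.leaf_labels)
            labels[GERMLINE] = "P"
            sites = tuple(sorted(set(labels.values())))
            hist, post = infer_bbm(ds.tree, labels, MkModel(len(sites)), sites=sites)
            assert hist.labeling[ds.tree.root] == "P"
            assert post.map_site(ds.tree.root) == "P"

    def test_map_ties_break_toward_parent(self):
        # perfectly symmetric cherry: internal posterior is (0.5, 0.5);
        # with the root tied too, alphabetical order gives M1 at the root
        # and the child follows its parent rather than flip-flopping
        tree = tree_from_nested((("A", "B"), "C"), prefix="x")
        tree.branch_lengths.update({"A": 1.0, "B": 1.0, "C": 1.0, "x1": 1.0})
        labels = {"A": "P", "B": "M1", "C": "M1"}
        hist, _ = infer_bbm(tree, labels, MkModel(2), sites=("M1", "P"))
        assert hist.labeling["x0"] == "M1"


class TestEventAnnotation:
    def test_dispersal_on_range_gain(self):
        tree = tree_from_nested(("A", "B"), prefix="x")
        ranges = {"x0": frozenset({"M1"}), "A": frozenset({"M1", "M7"}),
                  "B": frozenset({"M1"})}
        events = annotate_events(tree, ranges)
        disp = [e for e in events if e.kind == "dispersal"]
        assert disp == [BiogeoEvent("dispersal", "A", "M1→M7")]

    def test_diversification_on_shared_site(self):
        tree = tree_from_nested(("A", "B"), prefix="x")
        ranges = {"x0": frozenset({"M2"}), "A": frozenset({"M2"}),
                  "B": frozenset({"M2"})}
        events = annotate_events(tree, ranges)
        div = [e for e in events if e.kind == "diversification"]
        assert div == [BiogeoEvent("diversification", "x0", "M2^M2")]

    def test_extinction_on_range_loss(self):
        tree = tree_from_nested(("A", "B"), prefix="x")
        ranges = {"x0": frozenset({"M1", "M7"}), "A": frozenset({"M1"}),
                  "B": frozenset({"M1", "M7"})}
        events = annotate_events(tree, ranges)
        ext = [e for e in events if e.kind == "extinction"]
        assert ext == [BiogeoEvent("extinction", "A", "M7")]

    def test_empty_range_rejected(self):
        tree = tree_from_nested(("A", "B"), prefix="x")
        with pytest.raises(ValueError, match="empty"):
            annotate_events(tree, {"x0": frozenset(), "A": frozenset({"P"}),
                                   "B": frozenset({"P"})})

    def test_ranges_from_posterior_threshold(self):
        post = AncestralPosterior(
            ("M1", "M2", "P"),
            {"n": np.array([0.5, 0.3, 0.2]), "m": np.array([0.9, 0.07, 0.03])},
        )
        assert post.range_of("n", threshold=0.15) == frozenset({"M1", "M2", "P"})
        assert post.range_of("m", threshold=0.15) == frozenset({"M1"})
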