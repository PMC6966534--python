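"""Shared fixtures and independent brute-force oracles.

The oracles enumerate full labelings (or ancestral assignments) directly
and never call the dynamic programs they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from tumorbiogeo.phylo import ClonePhylogeny


# ---------------------------------------------------------------------------
# tree helpers

def tree_from_nested(nested, prefix="i"):
    """Build a ClonePhylogeny from nested tuples of leaf names.

    ``(("A", "B"), "C")`` is a rooted tree with a cherry (A,B) and C.
    """
    children = {}
    counter = itertools.count()

    def build(sub):
        if isinstance(sub, str):
            return sub
        name = f"{prefix}{next(counter)}"
        children[name] = [build(part) for part in sub]
        return name

    root = build(nested)
    return ClonePhylogeny(root, children)


def all_rooted_trees(leaves):
    """Every rooted tree (polytomies allowed, no unary nodes) on the leaves.

    Trees correspond to hierarchies: the root's children partition the
    leaf set into >= 2 blocks, each block recursively a tree.
    """
    leaves = list(leaves)
    if len(leaves) == 1:
        yield leaves[0]
        return
    for partition in _partitions(leaves):
        if len(partition) < 2:
            continue
        for combo in itertools.product(*(all_rooted_trees(b) for b in partition)):
            yield tuple(combo)


def _partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def random_tree(rng, n_leaves, polytomy_prob=0.0, max_len=6):
    """Random rooted tree by sequential joins, optionally multifurcating."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    children = {}
    counter = itertools.count()
    while len(nodes) > 1:
        k = 2
        if len(nodes) > 2 and rng.random() < polytomy_prob:
            k = 3
        picks = sorted(rng.choice(len(nodes), size=k, replace=False))
        name = f"I{next(counter)}"
        children[name] = [nodes[i] for i in picks]
        nodes = [n for i, n in enumerate(nodes) if i not in picks] + [name]
    lengths = {}
    tree = ClonePhylogeny(nodes[0], children)
    for v in tree.nodes:
        if v != tree.root:
            lengths[v] = float(rng.integers(1, max_len + 1))
    return ClonePhylogeny(nodes[0], children, lengths)


# ---------------------------------------------------------------------------
# parsimony oracle

def brute_force_pmh(tree, leaf_labels, sites, root_constraint=None):
    """(mu, gamma, sigma) by exhaustive enumeration of full labelings.

    gamma uses an explicit longest-chain computation over the migration
    edges of each ordered site pair, with ancestry decided by walking
    parent pointers (independent of the package's single-DFS counter).
    """
    internal = [v for v in tree.nodes if not tree.is_leaf(v)]
    best = None
    for combo in itertools.product(sites, repeat=len(internal)):
        lab = dict(leaf_labels)
        lab.update(dict(zip(internal, combo)))
        if root_constraint is not None and lab[tree.root] != root_constraint:
            continue
        mu = sum(1 for u, v in tree.edges() if lab[u] != lab[v])
        if best is not None and mu > best[0]:
            continue
        gamma = _brute_comigrations(tree, lab)
        sigma = len({lab[u] for u, v in tree.edges() if lab[u] != lab[v]})
        key = (mu, gamma, sigma)
        if best is None or key < best:
            best = key
    return best


def _is_ancestor(tree, a, b):
    while b is not None:
        if b == a:
            return True
        b = tree.parent.get(b)
    return False


def _brute_comigrations(tree, lab):
    pairs = {}
    for u, v in tree.edges():
        if lab[u] != lab[v]:
            pairs.setdefault((lab[u], lab[v]), []).append((u, v))
    total = 0
    for edges in pairs.values():
        # longest chain in the ancestor-descendant partial order
        n = len(edges)
        longest = 1
        order = sorted(range(n), key=lambda i: _depth(tree, edges[i][1]))
        chain = [1] * n
        for a in range(n):
            for b in range(a):
                ia, ib = order[a], order[b]
                if _is_ancestor(tree, edges[ib][1], edges[ia][0]) or (
                    edges[ib][1] == edges[ia][0]
                ):
                    chain[a] = max(chain[a], chain[b] + 1)
            longest = max(longest, chain[a])
        total += longest
    return total


def _depth(tree, v):
    d = 0
    while v != tree.root:
        v = tree.parent[v]
        d += 1
    return d


# ---------------------------------------------------------------------------
# Bayesian oracle

def brute_force_posteriors(tree, leaf_labels, model, sites):
    """Per-node marginals by summing over every full assignment."""
    index = {s: i for i, s in enumerate(sites)}
    k = len(sites)
    trans = {
        v: model.transition_matrix(tree.branch_length(v)) for v in tree.parent
    }
    internal = [v for v in tree.nodes if not tree.is_leaf(v)]
    post = {v: np.zeros(k) for v in tree.nodes}
    for combo in itertools.product(range(k), repeat=len(internal)):
        lab = {v: index[leaf_labels[v]] for v in tree.leaves}
        lab.update(dict(zip(internal, combo)))
        w = 1.0 / k  # uniform root prior
        for u, v in tree.edges():
            w *= trans[v][lab[u], lab[v]]
        for v in tree.nodes:
            post[v][lab[v]] += w
    for v in tree.nodes:
        post[v] /= post[v].sum()
    return post


@pytest.fixture
def rng():
    return np.random.default_rng(20231119)
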