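"""Bayesian ancestral tumor-site inference (biogeography-style, BBM-like).

Tumor sites are treated as discrete areas and clone dispersal between
them as a continuous-time Markov chain on the clone phylogeny, with equal
exchange rates between all sites (the k-state generalization of
Jukes-Cantor). Branch lengths are mutation counts scaled into expected
site changes. The root is constrained to the primary tumor indirectly,
by including the germline outgroup as a leaf observed at P on a
zero-length (pseudo-epsilon) branch.

Per-node marginal posteriors are available exactly (two-pass belief
propagation / Felsenstein pruning with a downward pass) or by Gibbs MCMC
over ancestral site assignments, run as several independent chains whose
post-burn-in samples are pooled. Inferred migration histories take the
maximum-a-posteriori site at every internal node.

Biogeographic events (dispersal, diversification, extinction) are
annotated on multi-site ranges obtained by thresholding the per-site
posterior mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .graphs import MigrationGraph
from .parsimony import MigrationHistory, count_comigrations, extract_migration_graph
from .phylo import ClonePhylogeny, GERMLINE, PRIMARY_SITE

__all__ = [
    "MkModel",
    "AncestralPosterior",
    "McmcConfig",
    "marginal_posteriors",
    "mcmc_sample",
    "infer_bbm",
    "annotate_events",
    "BiogeoEvent",
]


# ---------------------------------------------------------------------------
# model

@dataclass(frozen=True)
class MkModel:
    """Equal-rate k-state Markov model of clone dispersal between sites.

    Off-diagonal rates are all 1/(k-1), normalized so one unit of branch
    length is one expected site change. ``scale`` converts a branch length
    in mutations into expected site changes (the mutation clock and the
    dispersal clock are distinct; the default assumes one expected
    dispersal per 20 mutations). Zero-length branches are given the
    pseudo-length ``epsilon`` (in mutations) inside probability
    calculations only.
    """

    n_states: int
    scale: float = 0.05
    epsilon: float = 0.01

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError("need at least 2 tumor sites")
        if self.scale <= 0 or self.epsilon <= 0:
            raise ValueError("scale and epsilon must be positive")

    def transition_matrix(self, mutations: float) -> np.ndarray:
        """P[i, j] = Pr(site j at child | site i at parent)."""
        k = self.n_states
        t = max(float(mutations), self.epsilon) * self.scale
        e = math.exp(-k * t / (k - 1))
        same = 1.0 / k + (k - 1) / k * e
        diff = 1.0 / k - 1.0 / k * e
        p = np.full((k, k), diff)
        np.fill_diagonal(p, same)
        return p

    def stationary(self) -> np.ndarray:
        return np.full(self.n_states, 1.0 / self.n_states)


@dataclass
class AncestralPosterior:
    """Per-node posterior distributions over tumor sites."""

    sites: tuple[str, ...]
    probs: dict  # node -> np.ndarray of length k, sums to 1

    def prob(self, node: str, site: str) -> float:
        return float(self.probs[node][self.sites.index(site)])

    def map_site(self, node: str) -> str:
        p = self.probs[node]
        return self.sites[int(np.argmax(p))]

    def map_prob(self, node: str) -> float:
        return float(np.max(self.probs[node]))

    def range_of(self, node: str, threshold: float = 0.15) -> frozenset:
        """Sites with posterior mass >= threshold (always includes the MAP)."""
        p = self.probs[node]
        keep = {self.sites[i] for i in range(len(self.sites)) if p[i] >= threshold}
        keep.add(self.map_site(node))
        return frozenset(keep)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {node: p for node, p in self.probs.items()}, index=list(self.sites)
        ).T


@dataclass(frozen=True)
class McmcConfig:
    """Gibbs sampler settings.

    ``generations`` are single-node update steps; states are recorded every
    ``sample_interval`` generations and the first ``burnin_samples``
    recorded states of each chain are discarded, after which the chains
    are pooled.
    """

    chains: int = 3
    generations: int = 5_000_000
    sample_interval: int = 1000
    burnin_samples: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.burnin_samples >= self.generations // self.sample_interval:
            raise ValueError("burn-in consumes every sample; lengthen the run")


# ---------------------------------------------------------------------------
# exact marginals: pruning + downward pass

def _setup(
    tree: ClonePhylogeny,
    leaf_labels: Mapping[str, str],
    model: MkModel,
    sites: Sequence[str] | None,
):
    alphabet = tuple(sites) if sites is not None else tuple(
        sorted(set(leaf_labels.values()))
    )
    if model.n_states != len(alphabet):
        raise ValueError(
            f"model has {model.n_states} states but alphabet has {len(alphabet)}"
        )
    index = {s: i for i, s in enumerate(alphabet)}
    trans = {
        child: model.transition_matrix(tree.branch_length(child))
        for child in tree.parent
    }
    return alphabet, index, trans


def marginal_posteriors(
    tree: ClonePhylogeny,
    leaf_labels: Mapping[str, str],
    model: MkModel,
    sites: Sequence[str] | None = None,
) -> AncestralPosterior:
    """Exact per-node marginal posteriors of the ancestral tumor sites.

    Upward (pruning) pass computes subtree conditional likelihoods; the
    downward pass distributes the evidence outside each subtree. The root
    prior is uniform over sites; a germline outgroup leaf labeled P, when
    present, is simply one more observation and pins the root to P.
    """
    alphabet, index, trans = _setup(tree, leaf_labels, model, sites)
    k = len(alphabet)

    up: dict[str, np.ndarray] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            if v not in leaf_labels:
                raise ValueError(f"leaf {v!r} has no site label")
            vec = np.zeros(k)
            vec[index[leaf_labels[v]]] = 1.0
        else:
            vec = np.ones(k)
            for c in tree.children[v]:
                vec = vec * (trans[c] @ up[c])
            s = vec.sum()
            if s > 0:
                vec = vec / s  # rescale; marginals are normalized anyway
        up[v] = vec

    down: dict[str, np.ndarray] = {tree.root: model.stationary()}
    for v in tree.preorder():
        if tree.is_leaf(v):
            continue
        msgs = {c: trans[c] @ up[c] for c in tree.children[v]}
        for c in tree.children[v]:
            out = down[v].copy()
            for b in tree.children[v]:
                if b != c:
                    out = out * msgs[b]
            d = out @ trans[c]
            s = d.sum()
            down[c] = d / s if s > 0 else d

    probs: dict[str, np.ndarray] = {}
    for v in tree.preorder():
        p = down[v] * up[v]
        total = p.sum()
        if total <= 0:
            raise ValueError(f"zero posterior mass at node {v!r}")
        probs[v] = p / total
    return AncestralPosterior(alphabet, probs)


# ---------------------------------------------------------------------------
# MCMC (Gibbs over ancestral assignments)

def mcmc_sample(
    tree: ClonePhylogeny,
    leaf_labels: Mapping[str, str],
    model: MkModel,
    mcmc: McmcConfig,
    sites: Sequence[str] | None = None,
) -> tuple[AncestralPosterior, dict]:
    """Gibbs sampling of ancestral site assignments.

    Each generation resamples one uniformly chosen internal node from its
    full conditional given its parent's and children's current sites.
    Post-burn-in samples from all chains are pooled into empirical
    per-node site frequencies. Returns the posterior estimate and
    diagnostics including the maximum across-chain frequency spread.
    """
    alphabet, index, trans = _setup(tree, leaf_labels, model, sites)
    k = len(alphabet)
    nodes = list(tree.preorder())
    pos = {v: i for i, v in enumerate(nodes)}
    internal = [v for v in nodes if not tree.is_leaf(v)]
    internal_pos = np.array([pos[v] for v in internal])
    prior = model.stationary()

    # flat arrays for the sampler: per internal node, its parent transition
    # matrix (or the root prior broadcast) and its children's matrices
    parent_row = []  # (k, k) matrix whose [parent_state] row conditions v
    kids = []  # list of (child_pos, (k,k) matrix) per internal node
    parent_pos = np.zeros(len(internal), dtype=int)
    for i, v in enumerate(internal):
        if v == tree.root:
            parent_row.append(np.tile(prior, (k, 1)))
            parent_pos[i] = pos[v]  # self; row is constant anyway
        else:
            parent_row.append(trans[v])
            parent_pos[i] = pos[tree.parent[v]]
        kids.append([(pos[c], trans[c]) for c in tree.children[v]])

    master = np.random.SeedSequence(mcmc.seed)
    chain_seeds = master.spawn(mcmc.chains)

    pooled = np.zeros((len(internal), k))
    per_chain_freq = []
    n_samples_per_chain = mcmc.generations // mcmc.sample_interval - mcmc.burnin_samples

    leaf_state = {v: index[leaf_labels[v]] for v in tree.leaves}
    base_state = np.zeros(len(nodes), dtype=int)
    for v, s in leaf_state.items():
        base_state[pos[v]] = s

    n_int = len(internal)
    block = 4096
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        state = base_state.copy()
        state[internal_pos] = rng.integers(k, size=n_int)
        counts = np.zeros((n_int, k))
        n_recorded = 0
        gen = 0
        while gen < mcmc.generations:
            nblk = min(block, mcmc.generations - gen)
            picks = rng.integers(n_int, size=nblk)
            us = rng.random(nblk)
            for j in range(nblk):
                i = picks[j]
                w = parent_row[i][state[parent_pos[i]]]
                for cpos, pmat in kids[i]:
                    w = w * pmat[:, state[cpos]]
                cw = np.cumsum(w)
                state[internal_pos[i]] = np.searchsorted(cw, us[j] * cw[-1])
                gen += 1
                if gen % mcmc.sample_interval == 0:
                    n_recorded += 1
                    if n_recorded > mcmc.burnin_samples:
                        counts[np.arange(n_int), state[internal_pos]] += 1
        with np.errstate(invalid="ignore"):
            freq_arr = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1)
        per_chain_freq.append({v: freq_arr[i] for i, v in enumerate(internal)})
        pooled += counts
    pooled = {v: pooled[i] for i, v in enumerate(internal)}

    probs = {}
    for v in internal:
        total = pooled[v].sum()
        probs[v] = pooled[v] / total if total > 0 else np.full(k, 1.0 / k)
    for v, s in leaf_state.items():
        vec = np.zeros(k)
        vec[s] = 1.0
        probs[v] = vec

    spread = 0.0
    if mcmc.chains > 1:
        for v in internal:
            stack = np.stack([f[v] for f in per_chain_freq])
            spread = max(spread, float((stack.max(axis=0) - stack.min(axis=0)).max()))
    diagnostics = {
        "max_across_chain_spread": spread,
        "samples_per_chain": n_samples_per_chain,
        "pooled_samples": n_samples_per_chain * mcmc.chains,
    }
    return AncestralPosterior(alphabet, probs), diagnostics


# ---------------------------------------------------------------------------
# migration history from posteriors

def infer_bbm(
    tree: ClonePhylogeny,
    leaf_labels: Mapping[str, str],
    model: MkModel | None = None,
    mcmc: McmcConfig | None = None,
    estimator: str = "exact-pruning",
    primary: str = PRIMARY_SITE,
    germline: str = GERMLINE,
    sites: Sequence[str] | None = None,
) -> tuple[MigrationHistory, AncestralPosterior]:
    """Bayesian migration history: MAP ancestral site at every node.

    ``estimator`` is ``"exact-pruning"`` (default) or ``"mcmc"``. MAP ties
    are broken toward the parent's MAP site, then alphabetically, which
    avoids creating migration edges the posterior does not support. The
    germline leaf, if present in the tree, must carry the primary-site
    label; its edges are excluded from the migration graph.
    """
    alphabet = tuple(sites) if sites is not None else tuple(
        sorted(set(leaf_labels.values()))
    )
    if model is None:
        model = MkModel(n_states=len(alphabet))
    if estimator == "exact-pruning":
        post = marginal_posteriors(tree, leaf_labels, model, alphabet)
    elif estimator == "mcmc":
        post = mcmc_sample(tree, leaf_labels, model, mcmc or McmcConfig(), alphabet)[0]
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    labeling: dict[str, str] = {}
    tol = 1e-12
    for v in tree.preorder():
        if tree.is_leaf(v):
            labeling[v] = leaf_labels[v]
            continue
        p = post.probs[v]
        top = float(np.max(p))
        tied = [alphabet[i] for i in range(len(alphabet)) if p[i] >= top - tol]
        if len(tied) > 1 and v != tree.root:
            parent_site = labeling[tree.parent[v]]
            if parent_site in tied:
                labeling[v] = parent_site
                continue
        labeling[v] = sorted(tied)[0]

    exclude = [germline] if germline in tree.parent or germline == tree.root else []
    graph = extract_migration_graph(tree, labeling, primary, exclude, alphabet)
    gamma = count_comigrations(tree, labeling, exclude)
    history = MigrationHistory(
        labeling, graph, graph.n_migrations, gamma, graph.n_sources
    )
    return history, post


# ---------------------------------------------------------------------------
# biogeographic event annotation

@dataclass(frozen=True)
class BiogeoEvent:
    """A dispersal / diversification / extinction event on the tree.

    ``where`` is a child node for branch events (the event happens on the
    branch above it) or the node itself for diversification. ``label``
    uses arrow notation for dispersal (source->gained site) and caret
    notation for within-site diversification (site^site).
    """

    kind: str  # "dispersal" | "diversification" | "extinction"
    where: str
    label: str


def annotate_events(
    tree: ClonePhylogeny, ranges: Mapping[str, frozenset]
) -> list[BiogeoEvent]:
    """Annotate biogeographic events given per-node site ranges.

    Per branch: a dispersal for each site the child range gains (written
    from the lexicographically first retained parent site), an extinction
    for each site it loses. Per internal node: a diversification for each
    site retained by the node and both of its children (lineages diverge
    within that site).
    """
    events: list[BiogeoEvent] = []
    for v in tree.preorder():
        rv = ranges.get(v)
        if rv is not None and not rv:
            raise ValueError(f"empty site range at node {v!r}")
    for u, c in tree.edges():
        if u not in ranges or c not in ranges:
            continue
        ru, rc = ranges[u], ranges[c]
        gained = sorted(rc - ru)
        lost = sorted(ru - rc)
        kept = sorted(ru & rc)
        source = kept[0] if kept else sorted(ru)[0]
        for site in gained:
            events.append(BiogeoEvent("dispersal", c, f"{source}→{site}"))
        for site in lost:
            events.append(BiogeoEvent("extinction", c, f"{site}"))
    for v in tree.nodes:
        kids = tree.children.get(v, ())
        if len(kids) < 2 or v not in ranges:
            continue
        shared = ranges[v]
        for kid in kids:
            if kid in ranges:
                shared = shared & ranges[kid]
        for site in sorted(shared):
            events.append(BiogeoEvent("diversification", v, f"{site}^{site}"))
    return events


def events_to_tsv(events: Sequence[BiogeoEvent]) -> str:
    return "".join(f"{e.kind}\t{e.where}\t{e.label}\n" for e in events)
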