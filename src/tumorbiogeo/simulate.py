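"""Synthetic metastatic-seeding datasets with known migration histories.

Generates clone phylogenies, homoplasy-free binary mutation matrices,
leaf tumor-site labels, and the TRUE migration graph under four seeding
scenarios of increasing complexity:

- mS: monoclonal single-source seeding — every metastasis is founded by
  exactly one migrating clone from exactly one source site;
- pS: polyclonal single-source seeding — at least one metastasis receives
  two or more migrating clones, all from the same source site;
- pM: polyclonal multisource seeding — at least one metastasis receives
  migrating clones from two or more distinct source sites;
- pR: reseeding — at least one clone migrates from a metastasis back to
  the primary tumor.

The generator works at clone resolution: a migration-event plan satisfying
the scenario's constraints is drawn first, then a binary clone tree
realizing it is grown by a branching process in which each migration
splits a resident lineage, leaving one daughter at the source site and
placing the other at the target. Mutations accrue privately on every
branch, so the resulting binary character matrix is homoplasy-free and
the maximum-parsimony (perfect-phylogeny) tree equals the true tree.

Dataset sizes mimic multi-site tumor sequencing studies: 5-7 tumor
sites ("m5" class) or 8-11 ("m8"), 7-28 sampled clones, 9-99 characters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import MigrationGraph
from .phylo import (
    CloneMatrix,
    ClonePhylogeny,
    GERMLINE,
    PRIMARY_SITE,
    parse_edge_list,
    parse_newick,
    read_labeling,
    write_labeling,
)

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "classify_scenario",
    "write_dataset",
    "read_dataset",
    "SCENARIOS",
    "TUMOR_CLASSES",
]

SCENARIOS = ("mS", "pS", "pM", "pR")
TUMOR_CLASSES = {"m5": (5, 7), "m8": (8, 11)}


@dataclass(frozen=True)
class SimConfig:
    """Settings for one simulated dataset.

    Either ``tumor_class`` ("m5": 5-7 sites, "m8": 8-11 sites) or an
    explicit ``n_sites`` must be given. Clone and character totals are
    clamped to the benchmark ranges after the per-site and per-branch
    draws.
    """

    scenario: str
    tumor_class: str | None = None
    n_sites: int | None = None
    clones_per_site: tuple[int, int] = (1, 4)
    clone_range: tuple[int, int] = (7, 28)
    mutations_per_branch: tuple[int, int] = (1, 6)
    char_range: tuple[int, int] = (9, 99)
    reseed_prob: float = 0.3
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.n_sites is None and self.tumor_class is None:
            raise ValueError("give either tumor_class or n_sites")
        if self.tumor_class is not None and self.tumor_class not in TUMOR_CLASSES:
            raise ValueError(f"unknown tumor class {self.tumor_class!r}")
        if self.n_sites is not None and self.n_sites < 2:
            raise ValueError("need at least 2 tumor sites")


@dataclass
class SimulatedDataset:
    """A simulated dataset plus its full ground truth."""

    tree: ClonePhylogeny  # germline-rooted true clone phylogeny
    matrix: CloneMatrix | None
    leaf_labels: dict  # sampled clone -> site (germline excluded)
    true_labels: dict | None  # every node -> site
    true_graph: MigrationGraph | None
    scenario: str | None
    config: SimConfig | None = None

    @property
    def sites(self) -> tuple[str, ...]:
        if self.true_graph is not None:
            return tuple(sorted(self.true_graph.sites))
        return tuple(sorted(set(self.leaf_labels.values())))


def classify_scenario(graph: MigrationGraph) -> str:
    """Classify a migration graph into mS / pS / pM / pR.

    Precedence: reseeding (any edge into the primary) dominates; then
    multisource (a site seeded from >= 2 distinct sources); then
    polyclonal single-source (a site seeded >= 2 times from one source);
    otherwise monoclonal single-source.
    """
    p = graph.primary
    if any(t == p and m > 0 for (s, t), m in graph.edges.items()):
        return "pR"
    targets = {t for (s, t), m in graph.edges.items() if m > 0}
    for t in targets:
        if len(graph.in_sources(t)) >= 2:
            return "pM"
    for t in targets:
        if sum(graph.in_edges(t).values()) >= 2:
            return "pS"
    return "mS"


# ---------------------------------------------------------------------------
# generation

def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Draw one dataset; fully reproducible from ``config.seed``.

    Rejection-samples (bounded by ``config.max_attempts``) until the true
    migration graph classifies as the requested scenario and all size
    constraints hold.
    """
    rng = np.random.default_rng(config.seed)
    last_error = None
    for _ in range(config.max_attempts):
        try:
            ds = _simulate_once(config, rng)
        except _Unsatisfiable as exc:
            last_error = exc
            continue
        assert ds.true_graph is not None
        if classify_scenario(ds.true_graph) == config.scenario:
            return ds
    raise RuntimeError(
        f"could not satisfy scenario {config.scenario!r} constraints in "
        f"{config.max_attempts} attempts; try a larger clone budget"
        + (f" (last error: {last_error})" if last_error else "")
    )


class _Unsatisfiable(Exception):
    pass


def _draw_sites(config: SimConfig, rng: np.random.Generator) -> list[str]:
    if config.n_sites is not None:
        n = config.n_sites
    else:
        lo, hi = TUMOR_CLASSES[config.tumor_class]
        n = int(rng.integers(lo, hi + 1))
    return [PRIMARY_SITE] + [f"M{i}" for i in range(1, n)]


def _plan_migrations(
    config: SimConfig, sites: list[str], rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Ordered (source, target) migration events satisfying the scenario."""
    p = sites[0]
    mets = sites[1:]
    plan: list[tuple[str, str]] = []
    seeded = [p]
    # base plan: every metastasis founded once, mostly from the primary
    for m in mets:
        if len(seeded) == 1 or rng.random() < 0.7:
            src = p
        else:
            src = seeded[int(rng.integers(1, len(seeded)))]
        plan.append((src, m))
        seeded.append(m)

    base_source = {m: s for s, m in plan}
    scen = config.scenario
    if scen in ("pS", "pR") and (scen == "pS" or rng.random() < 0.5):
        # duplicate seeding(s) from the same source site
        n_extra = 1 + int(rng.integers(0, 2))
        for _ in range(n_extra):
            m = mets[int(rng.integers(len(mets)))]
            plan.append((base_source[m], m))
    if scen == "pM" or (scen == "pR" and rng.random() < 0.5):
        # seed some metastasis from a second, distinct source
        candidates = [
            m for m in mets if any(s != base_source[m] and s != m for s in sites)
        ]
        if not candidates:
            raise _Unsatisfiable("no multisource candidate")
        m = candidates[int(rng.integers(len(candidates)))]
        others = [s for s in sites if s not in (base_source[m], m)]
        plan.append((others[int(rng.integers(len(others)))], m))
    if scen == "pR":
        n_reseed = 1 + int(rng.random() < config.reseed_prob)
        for _ in range(n_reseed):
            src = mets[int(rng.integers(len(mets)))]
            plan.append((src, p))
    if scen != "pR":
        assert not any(t == p for _, t in plan)
    return plan


def _simulate_once(config: SimConfig, rng: np.random.Generator) -> SimulatedDataset:
    sites = _draw_sites(config, rng)
    plan = _plan_migrations(config, sites, rng)

    # --- grow a binary clone tree realizing the plan -----------------------
    # active lineages: pending leaf id -> current site
    counter = [0]

    def fresh() -> str:
        counter[0] += 1
        return f"v{counter[0]}"

    children: dict[str, list[str]] = {}
    node_site: dict[str, str] = {}
    mrca = fresh()
    node_site[mrca] = PRIMARY_SITE
    active: dict[str, str] = {mrca: PRIMARY_SITE}

    def branch(lineage: str, site_a: str, site_b: str) -> tuple[str, str]:
        a, b = fresh(), fresh()
        children[lineage] = [a, b]
        node_site[a], node_site[b] = site_a, site_b
        del active[lineage]
        active[a], active[b] = site_a, site_b
        return a, b

    # --- decide final clone counts per site ---------------------------------
    lo_c, hi_c = config.clones_per_site
    occupancy: dict[str, int] = {PRIMARY_SITE: 1}
    for _src, dst in plan:
        occupancy[dst] = occupancy.get(dst, 0) + 1
    targets = {
        s: max(occupancy[s], int(rng.integers(lo_c, hi_c + 1))) for s in occupancy
    }
    lo_n, hi_n = config.clone_range
    while sum(targets.values()) > hi_n:
        # shrink the largest headroom first
        cand = sorted(
            (s for s in targets if targets[s] > occupancy[s]),
            key=lambda s: (-(targets[s] - occupancy[s]), s),
        )
        if not cand:
            raise _Unsatisfiable("clone budget exceeded by migration plan")
        targets[cand[0]] -= 1
    while sum(targets.values()) < lo_n:
        s = sorted(targets)[int(rng.integers(len(targets)))]
        targets[s] += 1

    # --- interleave within-site expansion with the migration events ---------
    # a tumor keeps diversifying while it seeds others, so expansion
    # branchings are given random times relative to the migration sequence
    # (clamped so a site only expands once it is occupied)
    first_occupied = {PRIMARY_SITE: 0}
    for i, (_src, dst) in enumerate(plan):
        first_occupied.setdefault(dst, i + 1)
    expansions: list[tuple[int, str]] = []
    for s in sorted(targets):
        for _ in range(targets[s] - occupancy[s]):
            t = int(rng.integers(first_occupied[s], len(plan) + 1))
            expansions.append((t, s))

    events: list[tuple[str, str, str]] = []  # (kind, a, b)
    for i in range(len(plan) + 1):
        for t, s in expansions:
            if t == i:
                events.append(("expand", s, s))
        if i < len(plan):
            events.append(("migrate",) + plan[i])

    for kind, a, b in events:
        site = a if kind == "expand" else a
        residents = sorted(l for l, s in active.items() if s == site)
        if not residents:
            raise _Unsatisfiable(f"no resident lineage at {site}")
        lineage = residents[int(rng.integers(len(residents)))]
        branch(lineage, site, b if kind == "migrate" else site)

    # --- name sampled clones, attach germline, finalize tree ----------------
    per_site_count: dict[str, int] = {}
    rename: dict[str, str] = {}
    for v in sorted(active):
        s = active[v]
        per_site_count[s] = per_site_count.get(s, 0) + 1
        rename[v] = f"{s}_{per_site_count[s]}"

    def mapped(v: str) -> str:
        return rename.get(v, v)

    final_children = {
        mapped(u): [mapped(c) for c in cs] for u, cs in children.items()
    }
    node_site = {mapped(v): s for v, s in node_site.items()}
    root = "root"
    final_children[root] = [GERMLINE, mapped(mrca)]
    node_site[root] = PRIMARY_SITE
    node_site[GERMLINE] = PRIMARY_SITE

    # --- mutations: >=1 private character per non-germline edge -------------
    lo_m, hi_m = config.mutations_per_branch
    edge_children = [
        c
        for u, cs in final_children.items()
        for c in cs
        if c != GERMLINE
    ]
    edge_children.sort()
    muts = {c: int(rng.integers(lo_m, hi_m + 1)) for c in edge_children}
    lo_k, hi_k = config.char_range
    total = sum(muts.values())
    shrinkable = [c for c in edge_children if muts[c] > 1]
    while total > hi_k:
        if not shrinkable:
            raise _Unsatisfiable("character budget exceeded")
        c = shrinkable[int(rng.integers(len(shrinkable)))]
        muts[c] -= 1
        total -= 1
        if muts[c] == 1:
            shrinkable.remove(c)
    while total < lo_k:
        c = edge_children[int(rng.integers(len(edge_children)))]
        if muts[c] < hi_m:
            muts[c] += 1
            total += 1

    lengths = {c: float(m) for c, m in muts.items()}
    lengths[GERMLINE] = 0.0
    tree = ClonePhylogeny(root, final_children, lengths)

    # --- binary matrix: leaf genotype = union of path mutations --------------
    char_ids: dict[str, list[str]] = {}
    next_char = 1
    for c in edge_children:
        ids = [f"c{next_char + i}" for i in range(muts[c])]
        next_char += muts[c]
        char_ids[c] = ids
    all_chars = [f"c{i}" for i in range(1, total + 1)]
    leaves = [v for v in tree.leaves if v != GERMLINE]
    data = pd.DataFrame(0, index=leaves + [GERMLINE], columns=all_chars, dtype=int)
    for leaf in leaves:
        path = []
        v = leaf
        while v != root:
            path.append(v)
            v = tree.parent[v]
        for node in path:
            for ch in char_ids.get(node, ()):
                data.loc[leaf, ch] = 1
    matrix = CloneMatrix(data)

    leaf_labels = {v: node_site[v] for v in leaves}
    true_graph = _graph_from_labeling(tree, node_site, sites)

    return SimulatedDataset(
        tree=tree,
        matrix=matrix,
        leaf_labels=leaf_labels,
        true_labels=node_site,
        true_graph=true_graph,
        scenario=config.scenario,
        config=config,
    )


def _graph_from_labeling(
    tree: ClonePhylogeny, labels: dict, sites: list[str]
) -> MigrationGraph:
    pairs = []
    for u, c in tree.edges():
        if GERMLINE in (u, c):
            continue
        if labels[u] != labels[c]:
            pairs.append((labels[u], labels[c]))
    return MigrationGraph.from_pairs(pairs, PRIMARY_SITE, sites)


# ---------------------------------------------------------------------------
# dataset directory I/O

_FILES = {
    "matrix": "clones.tsv",
    "newick": "tree.newick",
    "edges": "T.tree",
    "labels": "T.labeling",
    "truth_labels": "truth.labeling",
    "truth_graph": "truth_graph.tsv",
    "meta": "meta.json",
}


def write_dataset(ds: SimulatedDataset, directory: str | Path) -> Path:
    """Write every component of a dataset to plain-text files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / _FILES["newick"]).write_text(ds.tree.to_newick())
    (d / _FILES["edges"]).write_text(ds.tree.to_edge_list())
    (d / _FILES["labels"]).write_text(write_labeling(ds.leaf_labels))
    if ds.matrix is not None:
        (d / _FILES["matrix"]).write_text(ds.matrix.to_tsv())
    if ds.true_labels is not None:
        (d / _FILES["truth_labels"]).write_text(write_labeling(ds.true_labels))
    if ds.true_graph is not None:
        (d / _FILES["truth_graph"]).write_text(ds.true_graph.to_tsv())
    meta = {
        "scenario": ds.scenario,
        "sites": list(ds.sites),
        "config": asdict(ds.config) if ds.config is not None else None,
    }
    (d / _FILES["meta"]).write_text(json.dumps(meta, indent=1, default=list))
    return d


def read_dataset(directory: str | Path) -> SimulatedDataset:
    """Read a dataset directory; truth components are optional.

    A benchmark-style directory holding only ``T.tree`` + ``T.labeling``
    yields a dataset with the truth fields set to ``None``.
    """
    d = Path(directory)
    if (d / _FILES["newick"]).exists():
        tree = parse_newick((d / _FILES["newick"]).read_text())
    elif (d / _FILES["edges"]).exists():
        tree = parse_edge_list((d / _FILES["edges"]).read_text().splitlines())
    else:
        raise FileNotFoundError(f"no tree file in {d}")
    lab_path = d / _FILES["labels"]
    if not lab_path.exists():
        raise FileNotFoundError(f"missing labeling file {lab_path}")
    leaf_labels = read_labeling(lab_path.read_text())

    matrix = None
    if (d / _FILES["matrix"]).exists():
        matrix = CloneMatrix.from_tsv((d / _FILES["matrix"]).read_text())
    true_labels = None
    if (d / _FILES["truth_labels"]).exists():
        true_labels = read_labeling((d / _FILES["truth_labels"]).read_text())
    scenario = None
    sites = None
    config = None
    if (d / _FILES["meta"]).exists():
        meta = json.loads((d / _FILES["meta"]).read_text())
        scenario = meta.get("scenario")
        sites = meta.get("sites")
        raw = meta.get("config")
        if raw is not None:
            raw = dict(raw)
            for key in ("clones_per_site", "clone_range", "mutations_per_branch",
                        "char_range"):
                if key in raw and raw[key] is not None:
                    raw[key] = tuple(raw[key])
            config = SimConfig(**raw)
    true_graph = None
    if (d / _FILES["truth_graph"]).exists():
        true_graph = MigrationGraph.from_tsv(
            (d / _FILES["truth_graph"]).read_text(), PRIMARY_SITE, sites
        )
    return SimulatedDataset(
        tree=tree,
        matrix=matrix,
        leaf_labels=leaf_labels,
        true_labels=true_labels,
        true_graph=true_graph,
        scenario=scenario,
        config=config,
    )
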