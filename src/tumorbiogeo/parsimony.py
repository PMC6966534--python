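"""Parsimonious migration-history inference (PMH-style).

Infers ancestral tumor sites on a clone phylogeny by Sankoff dynamic
programming with unit cost for every site change, minimizing
lexicographically

1. mu    — migrations: tree edges whose endpoint sites differ,
2. gamma — comigrations: groups of simultaneous migrations between the
           same ordered pair of sites (polyclonal seeding events),
3. sigma — number of distinct source sites of migrations,

optionally with the root constrained to the primary tumor, and with a
polytomy-resolving variant (PMH-TR) that searches binary refinements of
the input tree for histories with fewer migrations.

Comigrations are counted per ordered site pair as the minimum number of
antichains (with respect to the ancestor–descendant order on tree edges)
covering that pair's migration edges, which by Mirsky's theorem equals the
length of the longest ancestor–descendant chain among them: migrations
between the same pair of sites can be simultaneous (one comigration) only
if none lies on the ancestral path of another.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

from .graphs import MigrationGraph
from .phylo import ClonePhylogeny, PRIMARY_SITE

__all__ = [
    "MigrationHistory",
    "SankoffTables",
    "sankoff_min_migrations",
    "enumerate_optimal_labelings",
    "count_comigrations",
    "count_sources",
    "extract_migration_graph",
    "infer_pmh",
    "resolve_polytomies_pmh_tr",
    "DEFAULT_ENUMERATION_CAP",
]

DEFAULT_ENUMERATION_CAP = 10_000
_INF = math.inf


@dataclass(frozen=True)
class MigrationHistory:
    """A full ancestral-site labeling with its migration graph and counts."""

    labeling: dict  # node -> site, all nodes
    graph: MigrationGraph
    migrations: int
    comigrations: int
    sources: int

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.migrations, self.comigrations, self.sources)


@dataclass(frozen=True)
class SankoffTables:
    """Bottom-up Sankoff cost tables, enough to enumerate optima."""

    tree: ClonePhylogeny
    sites: tuple[str, ...]
    cost: dict  # node -> tuple of costs per site (alphabet order)
    root_constraint: str | None


def _site_alphabet(
    leaf_labels: Mapping[str, str], sites: Sequence[str] | None
) -> tuple[str, ...]:
    if sites is not None:
        return tuple(sites)
    return tuple(sorted(set(leaf_labels.values())))


def sankoff_min_migrations(
    tree: ClonePhylogeny,
    leaf_labels: Mapping[str, str],
    root_constraint: str | None = None,
    sites: Sequence[str] | None = None,
) -> tuple[int, SankoffTables]:
    """Minimum number of migrations over all full site labelings.

    ``root_constraint`` fixes the root's site (the primary tumor in the
    constrained mode); ``None`` allows any site at the root (plain Sankoff).
    """
    alphabet = _site_alphabet(leaf_labels, sites)
    index = {s: i for i, s in enumerate(alphabet)}
    if root_constraint is not None and root_constraint not in index:
        raise ValueError(
            f"root constraint {root_constraint!r} not in site alphabet {alphabet}"
        )
    k = len(alphabet)
    cost: dict[str, tuple[float, ...]] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            if v not in leaf_labels:
                raise ValueError(f"leaf {v!r} has no site label")
            c = [_INF] * k
            c[index[leaf_labels[v]]] = 0.0
            cost[v] = tuple(c)
        else:
            c = []
            for i in range(k):
                tot = 0.0
                for ch in tree.children[v]:
                    cc = cost[ch]
                    tot += min(
                        cc[j] + (0.0 if j == i else 1.0) for j in range(k)
                    )
                c.append(tot)
            cost[v] = tuple(c)
    root_cost = cost[tree.root]
    if root_constraint is not None:
        best = root_cost[index[root_constraint]]
    else:
        best = min(root_cost)
    if not math.isfinite(best):
        raise ValueError("no labeling satisfies the constraints")
    return int(best), SankoffTables(tree, alphabet, cost, root_constraint)


def enumerate_optimal_labelings(
    tables: SankoffTables, cap: int = DEFAULT_ENUMERATION_CAP
) -> tuple[list[dict], bool]:
    """All migration-minimal full labelings, truncated at ``cap``.

    Returns ``(labelings, truncated)``. The order is deterministic: sites
    are tried in alphabet order while assigning nodes from the root down.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    tree, alphabet, cost = tables.tree, tables.sites, tables.cost
    k = len(alphabet)
    index = {s: i for i, s in enumerate(alphabet)}

    root_cost = cost[tree.root]
    if tables.root_constraint is not None:
        root_choices = [index[tables.root_constraint]]
    else:
        best = min(root_cost)
        root_choices = [i for i in range(k) if root_cost[i] == best]

    out: list[dict] = []
    truncated = False

    # iterative DFS over (node, assigned-site) choices in preorder
    order = [v for v in tree.preorder()]

    def optimal_child_sites(child: str, parent_site_i: int) -> list[int]:
        cc = cost[child]
        vals = [cc[j] + (0.0 if j == parent_site_i else 1.0) for j in range(k)]
        best = min(vals)
        return [j for j in range(k) if vals[j] == best]

    def rec(pos: int, assignment: dict) -> bool:
        """Return False when the cap was hit."""
        nonlocal truncated
        if pos == len(order):
            out.append({v: alphabet[i] for v, i in assignment.items()})
            if len(out) >= cap:
                return False
            return True
        v = order[pos]
        if pos == 0:
            choices = root_choices
        else:
            p = tree.parent[v]
            choices = optimal_child_sites(v, assignment[p])
        for i in choices:
            assignment[v] = i
            if not rec(pos + 1, assignment):
                del assignment[v]
                return False
        assignment.pop(v, None)
        return True

    completed = rec(0, {})
    truncated = not completed and _has_more(tables, root_choices, len(out))
    return out, truncated


def _has_more(tables: SankoffTables, root_choices: list[int], emitted: int) -> bool:
    # count optima (capped) to decide whether truncation actually dropped any
    return _count_optima(tables, limit=emitted + 1) > emitted


def _count_optima(tables: SankoffTables, limit: int) -> int:
    """Number of migration-minimal labelings, saturating at ``limit``."""
    tree, alphabet, cost = tables.tree, tables.sites, tables.cost
    k = len(alphabet)
    index = {s: i for i, s in enumerate(alphabet)}

    counts: dict[str, list[int]] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            counts[v] = [1 if math.isfinite(cost[v][i]) else 0 for i in range(k)]
        else:
            row = []
            for i in range(k):
                prod = 1
                for ch in tree.children[v]:
                    cc = cost[ch]
                    vals = [cc[j] + (0.0 if j == i else 1.0) for j in range(k)]
                    best = min(vals)
                    n = sum(
                        counts[ch][j]
                        for j in range(k)
                        if vals[j] == best
                    )
                    prod = min(prod * n, limit)
                row.append(prod)
            counts[v] = row
    root_cost = cost[tree.root]
    if tables.root_constraint is not None:
        total = counts[tree.root][index[tables.root_constraint]]
    else:
        best = min(root_cost)
        total = sum(
            counts[tree.root][i] for i in range(k) if root_cost[i] == best
        )
    return min(total, limit)


# ---------------------------------------------------------------------------
# migration graph and count extraction

def extract_migration_graph(
    tree: ClonePhylogeny,
    full_labeling: Mapping[str, str],
    primary: str = PRIMARY_SITE,
    exclude: Sequence[str] = (),
    sites: Sequence[str] | None = None,
) -> MigrationGraph:
    """Migration graph induced by a full labeling.

    One directed edge per tree edge whose endpoint sites differ. Edges
    incident to nodes in ``exclude`` (the germline taxon) are skipped.
    """
    skip = set(exclude)
    pairs = []
    for u, v in tree.edges():
        if u in skip or v in skip:
            continue
        su, sv = full_labeling[u], full_labeling[v]
        if su != sv:
            pairs.append((su, sv))
    site_set = set(sites or ()) | set(
        full_labeling[n] for n in tree.nodes if n not in skip
    )
    return MigrationGraph.from_pairs(pairs, primary, site_set)


def count_comigrations(
    tree: ClonePhylogeny,
    full_labeling: Mapping[str, str],
    exclude: Sequence[str] = (),
) -> int:
    """Number of comigration events implied by a full labeling.

    Per ordered site pair (s, t) the s->t migration edges that lie on a
    common root-to-leaf path cannot be simultaneous, so the pair
    contributes the length of its longest such chain (= minimum antichain
    cover). Computed in one DFS carrying per-pair on-path edge counts.
    """
    skip = set(exclude)
    best: dict[tuple[str, str], int] = {}
    depth: dict[tuple[str, str], int] = {}

    def dfs(v: str) -> None:
        for c in tree.children.get(v, ()):
            if c in skip or v in skip:
                if c not in skip:
                    dfs(c)
                continue
            su, sv = full_labeling[v], full_labeling[c]
            key = None
            if su != sv:
                key = (su, sv)
                depth[key] = depth.get(key, 0) + 1
                if depth[key] > best.get(key, 0):
                    best[key] = depth[key]
            dfs(c)
            if key is not None:
                depth[key] -= 1

    dfs(tree.root)
    return sum(best.values())


def count_sources(graph: MigrationGraph) -> int:
    return graph.n_sources


# ---------------------------------------------------------------------------
# full PMH inference

def infer_pmh(
    tree: ClonePhylogeny,
    leaf_labels: Mapping[str, str],
    root_constraint: str | None = PRIMARY_SITE,
    cap: int = DEFAULT_ENUMERATION_CAP,
    primary: str = PRIMARY_SITE,
    sites: Sequence[str] | None = None,
) -> MigrationHistory:
    """Parsimonious migration history on a fixed tree (PMH-con style).

    Among all labelings with the minimum number of migrations (enumerated
    up to ``cap``), returns the one minimizing (comigrations, sources)
    lexicographically; remaining ties are broken by the deterministic
    enumeration order.
    """
    mu, tables = sankoff_min_migrations(tree, leaf_labels, root_constraint, sites)
    labelings, _truncated = enumerate_optimal_labelings(tables, cap)
    best: MigrationHistory | None = None
    for lab in labelings:
        graph = extract_migration_graph(tree, lab, primary, sites=tables.sites)
        gamma = count_comigrations(tree, lab)
        sigma = graph.n_sources
        hist = MigrationHistory(lab, graph, graph.n_migrations, gamma, sigma)
        assert hist.migrations == mu, "labeling inconsistent with DP optimum"
        if best is None or (hist.comigrations, hist.sources) < (
            best.comigrations,
            best.sources,
        ):
            best = hist
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# PMH-TR: polytomy resolution

def _binary_resolutions(items: Sequence[str]) -> Iterator[object]:
    """All rooted binary tree shapes over ``items`` (nested 2-tuples).

    The number of shapes for n items is (2n-3)!!; each is generated once,
    by recursive bipartition with the first item anchored to the left part.
    """
    items = list(items)
    if len(items) == 1:
        yield items[0]
        return
    first, rest = items[0], items[1:]
    n = len(rest)
    for r in range(0, n):
        for combo in itertools.combinations(range(n), r):
            left = [first] + [rest[i] for i in combo]
            right = [rest[i] for i in range(n) if i not in combo]
            if not right:
                continue
            for lt in _binary_resolutions(left):
                for rt in _binary_resolutions(right):
                    yield (lt, rt)


def _graft(
    tree: ClonePhylogeny, node: str, shape: object, fresh: Iterator[str]
) -> ClonePhylogeny:
    """Replace the polytomy at ``node`` with a binary shape over its children.

    New internal edges get branch length 0 (no mutations support them)."""
    children = {u: list(cs) for u, cs in tree.children.items()}
    lengths = dict(tree.branch_lengths)

    def build(sub, parent: str) -> str:
        if isinstance(sub, str):
            children.setdefault(parent, []).append(sub)
            return sub
        name = next(fresh)
        children.setdefault(parent, []).append(name)
        lengths[name] = 0.0
        for part in sub:
            build(part, name)
        return name

    assert isinstance(shape, tuple) and len(shape) == 2
    children[node] = []
    for part in shape:
        build(part, node)
    return ClonePhylogeny(tree.root, children, lengths)


def resolve_polytomies_pmh_tr(
    tree: ClonePhylogeny,
    leaf_labels: Mapping[str, str],
    root_constraint: str | None = PRIMARY_SITE,
    cap: int = DEFAULT_ENUMERATION_CAP,
    primary: str = PRIMARY_SITE,
    sites: Sequence[str] | None = None,
    exhaustive_threshold: int = 6,
    local_search: bool = True,
) -> tuple[ClonePhylogeny, MigrationHistory]:
    """PMH with tree resolution (PMH-TR style).

    Resolves every polytomy into binary branching, searching for the
    refinement whose parsimonious history minimizes (migrations,
    comigrations, sources). Polytomies with at most ``exhaustive_threshold``
    children are searched exhaustively ((2n-3)!! shapes); larger ones are
    resolved by greedy pairwise joining unless ``local_search`` is off.
    Every clade of the input tree is preserved (the output refines the
    input), so the minimum migration count can only decrease or stay equal
    relative to the unresolved tree.
    """
    fresh = _fresh_names(tree)
    current = tree.copy()
    # resolve polytomies one at a time, deepest first so that node ids
    # remain valid as the tree is refined above them
    for node in _polytomies_postorder(current):
        degree = len(current.children[node])
        if degree <= exhaustive_threshold:
            best_tree, best_key = None, None
            for shape in _binary_resolutions(current.children[node]):
                cand = _graft(current, node, shape, fresh)
                key = _history_key(cand, leaf_labels, root_constraint, cap, sites)
                if best_key is None or key < best_key:
                    best_key, best_tree = key, cand
            assert best_tree is not None
            current = best_tree
        elif local_search:
            current = _greedy_resolve(
                current, node, leaf_labels, root_constraint, fresh, sites
            )
        else:
            raise ValueError(
                f"polytomy at {node!r} has {degree} children, above the "
                f"exhaustive threshold, and local search is disabled"
            )
    history = infer_pmh(current, leaf_labels, root_constraint, cap, primary, sites)
    return current, history


def _fresh_names(tree: ClonePhylogeny) -> Iterator[str]:
    used = set(tree.nodes)
    i = 0
    while True:
        name = f"r{i}"
        if name not in used:
            yield name
        i += 1


def _polytomies_postorder(tree: ClonePhylogeny) -> list[str]:
    return [v for v in tree.postorder() if len(tree.children.get(v, ())) > 2]


def _history_key(
    tree: ClonePhylogeny,
    leaf_labels: Mapping[str, str],
    root_constraint: str | None,
    cap: int,
    sites: Sequence[str] | None,
) -> tuple[int, int, int]:
    hist = infer_pmh(tree, leaf_labels, root_constraint, cap, sites=sites)
    return hist.counts


def _greedy_resolve(
    tree: ClonePhylogeny,
    node: str,
    leaf_labels: Mapping[str, str],
    root_constraint: str | None,
    fresh: Iterator[str],
    sites: Sequence[str] | None,
) -> ClonePhylogeny:
    """Resolve a large polytomy by repeatedly joining the best pair.

    At each step, every pair of current children of the polytomy is
    joined tentatively and the pair giving the smallest Sankoff migration
    minimum is kept (ties by order); quadratic in degree."""
    current = tree
    while len(current.children[node]) > 2:
        kids = current.children[node]
        best = None
        for a, b in itertools.combinations(range(len(kids)), 2):
            cand = _join_pair(current, node, kids[a], kids[b], fresh)
            mu, _ = sankoff_min_migrations(
                cand, leaf_labels, root_constraint, sites
            )
            if best is None or mu < best[0]:
                best = (mu, cand)
        assert best is not None
        current = best[1]
    return current


def _join_pair(
    tree: ClonePhylogeny, node: str, a: str, b: str, fresh: Iterator[str]
) -> ClonePhylogeny:
    children = {u: list(cs) for u, cs in tree.children.items()}
    lengths = dict(tree.branch_lengths)
    name = next(fresh)
    children[node] = [c for c in children[node] if c not in (a, b)]
    children[node].append(name)
    children[name] = [a, b]
    lengths[name] = 0.0
    return ClonePhylogeny(tree.root, children, lengths)
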