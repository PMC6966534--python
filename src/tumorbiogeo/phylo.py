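"""Clone phylogenies, binary mutation matrices, and tumor-site labelings.

Core containers for tumor biogeography analyses: rooted clone trees whose
branch lengths count somatic mutations, homoplasy-free binary character
matrices (0 = germline base, 1 = substitution), and labelings that map
clones to the tumor sites they were sampled from.

Maximum-parsimony tree reconstruction is provided for homoplasy-free data
only, where it reduces to perfect-phylogeny construction and is guaranteed
to recover the generating topology.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import dendropy
import pandas as pd

PRIMARY_SITE = "P"
GERMLINE = "germline"

__all__ = [
    "ClonePhylogeny",
    "CloneMatrix",
    "TreeStructureError",
    "CycleError",
    "MultipleRootsError",
    "DuplicateNodeError",
    "HomoplasyError",
    "parse_tree",
    "parse_newick",
    "parse_edge_list",
    "read_labeling",
    "write_labeling",
    "reconstruct_mp_tree",
    "root_with_germline",
    "PRIMARY_SITE",
    "GERMLINE",
]


# ---------------------------------------------------------------------------
# errors

class TreeStructureError(ValueError):
    """Input does not describe a valid rooted tree."""


class CycleError(TreeStructureError):
    """A directed cycle was found among the edges."""


class MultipleRootsError(TreeStructureError):
    """More than one node has no parent."""


class DuplicateNodeError(TreeStructureError):
    """A node appears with two parents, or a leaf name is repeated."""


class HomoplasyError(ValueError):
    """Two binary characters violate the perfect-phylogeny condition."""

    def __init__(self, char_a: str, char_b: str):
        self.characters = (char_a, char_b)
        super().__init__(
            f"characters {char_a!r} and {char_b!r} are incompatible: their "
            "1-sets overlap without nesting (homoplasy or sample error)"
        )


# ---------------------------------------------------------------------------
# ClonePhylogeny

class ClonePhylogeny:
    """Rooted clone tree with integer mutation counts as branch lengths.

    Parameters
    ----------
    root : str
        Name of the root node.
    children : mapping node -> ordered list of children
        Nodes without an entry (or with an empty list) are leaves.
    branch_lengths : mapping child -> length, optional
        Number of mutations on the edge above each non-root node.
        Missing entries default to 1.
    """

    def __init__(
        self,
        root: str,
        children: Mapping[str, list[str]],
        branch_lengths: Mapping[str, float] | None = None,
    ):
        self.root = root
        self.children: dict[str, list[str]] = {
            u: list(cs) for u, cs in children.items() if cs
        }
        self.branch_lengths: dict[str, float] = dict(branch_lengths or {})
        self.parent: dict[str, str] = {}
        for u, cs in self.children.items():
            for c in cs:
                if c in self.parent:
                    raise DuplicateNodeError(
                        f"node {c!r} has two parents: {self.parent[c]!r} and {u!r}"
                    )
                self.parent[c] = u
        self._validate()

    def _validate(self) -> None:
        if self.root in self.parent:
            raise MultipleRootsError(f"declared root {self.root!r} has a parent")
        # every non-root node mentioned must be reachable from the root
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise CycleError(f"cycle detected through node {v!r}")
            seen.add(v)
            stack.extend(self.children.get(v, ()))
        mentioned = set(self.children) | set(self.parent) | {self.root}
        unreachable = mentioned - seen
        if unreachable:
            raise CycleError(
                f"nodes unreachable from root (cycle or disconnection): "
                f"{sorted(unreachable)}"
            )
        for child in self.branch_lengths:
            if self.branch_lengths[child] < 0:
                raise TreeStructureError(f"negative branch length above {child!r}")

    # -- traversal ---------------------------------------------------------

    def is_leaf(self, v: str) -> bool:
        return v not in self.children

    @property
    def leaves(self) -> list[str]:
        return [v for v in self.preorder() if self.is_leaf(v)]

    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self.children.get(v, ())))

    def postorder(self) -> Iterator[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children.get(v, ()))
        return iter(reversed(out))

    @property
    def nodes(self) -> list[str]:
        return list(self.preorder())

    def edges(self) -> Iterator[tuple[str, str]]:
        """Yield (parent, child) pairs in preorder."""
        for v in self.preorder():
            for c in self.children.get(v, ()):
                yield (v, c)

    def branch_length(self, child: str, default: float = 1.0) -> float:
        return self.branch_lengths.get(child, default)

    def is_binary(self) -> bool:
        return all(len(cs) == 2 for cs in self.children.values())

    def polytomies(self) -> list[str]:
        return [v for v, cs in self.children.items() if len(cs) > 2]

    def leaf_clades(self) -> set[frozenset[str]]:
        """Set of leaf sets subtended by each internal node (topology key)."""
        below: dict[str, frozenset[str]] = {}
        for v in self.postorder():
            if self.is_leaf(v):
                below[v] = frozenset([v])
            else:
                below[v] = frozenset().union(*(below[c] for c in self.children[v]))
        return {below[v] for v in self.children}

    def copy(self) -> "ClonePhylogeny":
        return ClonePhylogeny(self.root, self.children, self.branch_lengths)

    def without_leaf(self, leaf: str) -> "ClonePhylogeny":
        """Drop a leaf and suppress any resulting unifurcation."""
        if leaf not in self.parent or not self.is_leaf(leaf):
            raise TreeStructureError(f"{leaf!r} is not a leaf of this tree")
        children = {u: [c for c in cs if c != leaf] for u, cs in self.children.items()}
        lengths = {c: l for c, l in self.branch_lengths.items() if c != leaf}
        root = self.root
        p = self.parent[leaf]
        if len(children[p]) == 1:
            only = children[p][0]
            if p == root:
                root = only
                lengths.pop(only, None)
            else:
                gp = self.parent[p]
                children[gp] = [only if c == p else c for c in children[gp]]
                lengths[only] = lengths.get(only, 1.0) + lengths.pop(p, 1.0)
            del children[p]
        return ClonePhylogeny(root, children, lengths)

    # -- serialization -----------------------------------------------------

    def to_newick(self, with_lengths: bool = True) -> str:
        def fmt(v: str) -> str:
            label = v
            if self.is_leaf(v):
                s = label
            else:
                inner = ",".join(fmt(c) for c in self.children[v])
                s = f"({inner}){label}"
            if with_lengths and v in self.branch_lengths:
                bl = self.branch_lengths[v]
                s += f":{int(bl) if float(bl).is_integer() else bl}"
            return s

        return fmt(self.root) + ";"

    def to_edge_list(self) -> str:
        return "".join(f"{u} {c}\n" for u, c in self.edges())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClonePhylogeny):
            return NotImplemented
        return (
            self.root == other.root
            and {u: list(cs) for u, cs in self.children.items()} == other.children
            and self.branch_lengths == other.branch_lengths
        )

    def __repr__(self) -> str:
        return (
            f"ClonePhylogeny(root={self.root!r}, "
            f"{len(self.leaves)} leaves, {len(self.children)} internal nodes)"
        )


# ---------------------------------------------------------------------------
# parsing

def parse_newick(text: str) -> ClonePhylogeny:
    """Parse a newick string into a :class:`ClonePhylogeny`.

    Unnamed internal nodes receive deterministic ids ``n0, n1, ...`` in
    preorder. Branch lengths, when present, are preserved.
    """
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
    )
    counter = 0
    names: dict[int, str] = {}
    seen: set[str] = set()

    def name_of(node) -> str:
        nonlocal counter
        key = id(node)
        if key in names:
            return names[key]
        label = None
        if node.taxon is not None and node.taxon.label:
            label = node.taxon.label
        elif node.label:
            label = node.label
        if label is None:
            while f"n{counter}" in seen:
                counter += 1
            label = f"n{counter}"
            counter += 1
        if label in seen:
            raise DuplicateNodeError(f"duplicate node name {label!r} in newick")
        seen.add(label)
        names[key] = label
        return label

    children: dict[str, list[str]] = {}
    lengths: dict[str, float] = {}
    root_name = None
    for node in dtree.preorder_node_iter():
        v = name_of(node)
        if node.parent_node is None:
            root_name = v
        else:
            if node.edge.length is not None:
                lengths[v] = node.edge.length
        kids = [name_of(c) for c in node.child_nodes()]
        if kids:
            children[v] = kids
    assert root_name is not None
    return ClonePhylogeny(root_name, children, lengths)


def parse_edge_list(lines: Iterable[str]) -> ClonePhylogeny:
    """Parse "parent child" lines (a plain-text ``.tree`` edge list)."""
    children: dict[str, list[str]] = {}
    parent: dict[str, str] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise TreeStructureError(
                f"line {lineno}: expected 'parent child', got {line!r}"
            )
        u, c = parts
        if c in parent:
            raise DuplicateNodeError(
                f"line {lineno}: node {c!r} has two parents "
                f"({parent[c]!r} and {u!r})"
            )
        parent[c] = u
        children.setdefault(u, []).append(c)
    if not children:
        raise TreeStructureError("empty edge list")
    roots = [u for u in children if u not in parent]
    if not roots:
        raise CycleError("no root found: every node has a parent (cycle)")
    if len(roots) > 1:
        raise MultipleRootsError(f"multiple roots found: {sorted(roots)}")
    return ClonePhylogeny(roots[0], children)


def parse_tree(source: str | Iterable[str], fmt: str = "newick") -> ClonePhylogeny:
    """Parse a tree from newick text or an edge-list.

    ``fmt`` is ``"newick"`` or ``"edge-list"``.
    """
    if fmt == "newick":
        if not isinstance(source, str):
            source = "".join(source)
        return parse_newick(source)
    if fmt == "edge-list":
        if isinstance(source, str):
            source = source.splitlines()
        return parse_edge_list(source)
    raise ValueError(f"unknown tree format {fmt!r}")


# ---------------------------------------------------------------------------
# site labelings (plain dict node -> site, with file helpers)

def read_labeling(lines: Iterable[str] | str) -> dict[str, str]:
    """Read a two-column "node site" labeling file."""
    if isinstance(lines, str):
        lines = lines.splitlines()
    out: dict[str, str] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'node site', got {line!r}")
        node, site = parts
        if node in out:
            raise ValueError(f"line {lineno}: node {node!r} labeled twice")
        out[node] = site
    return out


def write_labeling(labeling: Mapping[str, str]) -> str:
    return "".join(f"{node} {site}\n" for node, site in labeling.items())


# ---------------------------------------------------------------------------
# CloneMatrix

@dataclass
class CloneMatrix:
    """Binary clones x characters matrix (0 = germline base, 1 = mutated).

    ``data`` is a pandas DataFrame with clone names as the index and
    character ids as columns, entries in {0, 1}.
    """

    data: pd.DataFrame

    def __post_init__(self):
        vals = self.data.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("clone matrix entries must be 0 or 1")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DuplicateNodeError(f"duplicate clone name {dup!r} in matrix")

    @property
    def clones(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def ones_of(self, char: str) -> frozenset[str]:
        col = self.data[char]
        return frozenset(col.index[col == 1])

    def check_compatibility(self) -> None:
        """Raise :class:`HomoplasyError` unless a perfect phylogeny exists.

        Binary characters are compatible iff, for every pair, their 1-sets
        are nested or disjoint (the rooted analogue of the four-gamete test
        with the germline fixing state 0 as ancestral).
        """
        chars = self.characters
        sets = {c: self.ones_of(c) for c in chars}
        for i, a in enumerate(chars):
            sa = sets[a]
            for b in chars[i + 1:]:
                sb = sets[b]
                inter = sa & sb
                if inter and not (sa <= sb or sb <= sa):
                    raise HomoplasyError(a, b)

    def with_germline(self, name: str = GERMLINE) -> "CloneMatrix":
        """Return a copy guaranteed to contain an all-zero germline row."""
        if name in self.data.index:
            if self.data.loc[name].any():
                raise ValueError(f"germline row {name!r} is not all zeros")
            return self
        zeros = pd.DataFrame(
            0, index=[name], columns=self.data.columns, dtype=self.data.dtypes.iloc[0]
            if len(self.data.dtypes) else int,
        )
        return CloneMatrix(pd.concat([self.data, zeros]))

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.data.to_csv(buf, sep="\t", index_label="clone")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "CloneMatrix":
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
        df.columns = [str(c) for c in df.columns]
        df.index = [str(i) for i in df.index]
        return cls(df.astype(int))


# ---------------------------------------------------------------------------
# maximum parsimony on homoplasy-free binary characters (perfect phylogeny)

def reconstruct_mp_tree(
    matrix: CloneMatrix, germline: str = GERMLINE
) -> ClonePhylogeny:
    """Reconstruct the clone phylogeny from a homoplasy-free binary matrix.

    With no homoplasy, maximum parsimony has a unique solution: the perfect
    phylogeny in which every character mutates exactly once. The tree is
    rooted at the germline genotype (all zeros); the germline taxon, added
    if absent, hangs off the root with branch length 0. Each edge's branch
    length is the number of characters mutating on it, so the parsimony
    score of the returned tree equals the number of characters.

    Identical columns are merged onto one edge; clones whose genotype
    coincides with an internal genotype (ancestral sampled clones) or with
    another clone become zero-length pendant leaves.
    """
    matrix = matrix.with_germline(germline)
    matrix.check_compatibility()

    chars = matrix.characters
    clone_names = [c for c in matrix.clones if c != germline]

    # group identical columns: one tree edge per distinct clone subset
    groups: dict[frozenset[str], list[str]] = {}
    for ch in chars:
        ones = matrix.ones_of(ch)
        if not ones:
            # character mutates in no sampled clone: place nowhere
            continue
        groups.setdefault(ones, []).append(ch)
    # sort by decreasing support, ties by first character id for determinism
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[0]), kv[1][0]))
    group_index = {ones: i for i, (ones, _) in enumerate(ordered)}

    # trie over per-clone sorted character-group paths
    root = "root"
    children: dict[str, list[str]] = {}
    lengths: dict[str, float] = {}
    trie_edges: dict[tuple[str, int], str] = {}  # (node, group) -> child
    fresh = iter(f"v{i}" for i in range(10**9))

    def attach(parent: str, child: str, length: float) -> None:
        children.setdefault(parent, []).append(child)
        lengths[child] = length

    genotype_node: dict[str, str] = {}
    for clone in clone_names:
        row = matrix.data.loc[clone]
        path = sorted(
            (group_index[ones] for ones, cs in groups.items() if clone in ones),
        )
        node = root
        for g in path:
            key = (node, g)
            if key not in trie_edges:
                nxt = next(fresh)
                attach(node, nxt, float(len(ordered[g][1])))
                trie_edges[key] = nxt
            node = trie_edges[key]
        genotype_node[clone] = node

    for clone in clone_names:
        attach(genotype_node[clone], clone, 0.0)
    attach(root, germline, 0.0)

    tree = ClonePhylogeny(root, children, lengths)
    return _suppress_unifurcations(tree)


def _suppress_unifurcations(tree: ClonePhylogeny) -> ClonePhylogeny:
    children = {u: list(cs) for u, cs in tree.children.items()}
    lengths = dict(tree.branch_lengths)
    root = tree.root
    changed = True
    while changed:
        changed = False
        for v, cs in list(children.items()):
            if len(cs) == 1 and v != root:
                only = cs[0]
                gp = tree.parent.get(v)
                # recompute parent from current structure
                gp = next(u for u, kk in children.items() if v in kk)
                children[gp] = [only if c == v else c for c in children[gp]]
                lengths[only] = lengths.get(only, 0.0) + lengths.pop(v, 0.0)
                del children[v]
                changed = True
                break
            if len(cs) == 1 and v == root:
                only = cs[0]
                del children[v]
                lengths.pop(only, None)
                root = only
                changed = True
                break
    return ClonePhylogeny(root, children, lengths)


# ---------------------------------------------------------------------------
# germline rooting

def root_with_germline(
    tree: ClonePhylogeny,
    germline_name: str = GERMLINE,
    primary_site: str = PRIMARY_SITE,
) -> tuple[ClonePhylogeny, dict[str, str]]:
    """Root a clone tree on the germline-incident edge.

    The germline taxon is the natural outgroup of a clone phylogeny (no
    somatic mutations), and its location is the primary tumor. Returns the
    rerooted tree and a labeling assigning ``primary_site`` to the germline
    leaf. A tree whose germline is already a child of the root is returned
    unchanged.
    """
    if germline_name not in tree.parent and germline_name != tree.root:
        raise TreeStructureError(f"germline leaf {germline_name!r} absent from tree")
    if not tree.is_leaf(germline_name):
        raise TreeStructureError(f"germline {germline_name!r} is not a leaf")
    if tree.parent.get(germline_name) == tree.root:
        return tree, {germline_name: primary_site}

    # re-hang the tree from the germline's parent upward: reverse the
    # parent chain from that node to the old root
    g = germline_name
    p = tree.parent[g]
    children = {u: list(cs) for u, cs in tree.children.items()}
    lengths = dict(tree.branch_lengths)

    path = [p]
    while path[-1] != tree.root:
        path.append(tree.parent[path[-1]])
    # reverse edges along path: path[i+1] becomes child of path[i]
    for lo, hi in zip(path, path[1:]):
        children[hi].remove(lo)
        children.setdefault(lo, []).append(hi)
        lengths[hi] = lengths.pop(lo, 1.0)
    # suppress old root if left with a single child
    old_root = tree.root
    if len(children.get(old_root, [])) == 1:
        only = children[old_root][0]
        holder = next(u for u, cs in children.items() if old_root in cs)
        children[holder] = [only if c == old_root else c for c in children[holder]]
        lengths[only] = lengths.get(only, 0.0) + lengths.pop(old_root, 0.0)
        del children[old_root]
    new_tree = ClonePhylogeny(p, children, lengths)
    return new_tree, {germline_name: primary_site}
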