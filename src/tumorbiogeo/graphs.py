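"""Directed multigraphs of clone migrations between tumor sites.

A migration graph has tumor sites (P, M1, ..., M10) as vertices and one
directed edge per clone migration event; polyclonal seeding of the same
site from the same source appears as edge multiplicity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .phylo import PRIMARY_SITE

__all__ = ["MigrationGraph"]


@dataclass(frozen=True)
class MigrationGraph:
    """Multiset of directed site->site migration edges.

    Parameters
    ----------
    edges : Counter mapping (source, target) -> multiplicity
    primary : designated primary tumor site
    sites : the full site alphabet of the dataset (a site may be isolated)
    """

    edges: Counter
    primary: str = PRIMARY_SITE
    sites: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        primary: str = PRIMARY_SITE,
        sites: Iterable[str] | None = None,
    ) -> "MigrationGraph":
        edges = Counter(tuple(p) for p in pairs)
        all_sites = set(sites or ())
        for s, t in edges:
            all_sites.update((s, t))
        all_sites.add(primary)
        return cls(edges, primary, frozenset(all_sites))

    # -- basic accessors ---------------------------------------------------

    @property
    def n_migrations(self) -> int:
        """Total edge multiplicity (number of migration events)."""
        return sum(self.edges.values())

    @property
    def n_sources(self) -> int:
        """Number of distinct sites that act as a migration source."""
        return len({s for (s, _t), m in self.edges.items() if m > 0})

    def multiplicity(self, source: str, target: str) -> int:
        return self.edges.get((source, target), 0)

    def in_edges(self, site: str) -> Counter:
        return Counter(
            {(s, t): m for (s, t), m in self.edges.items() if t == site and m > 0}
        )

    def in_sources(self, site: str) -> set[str]:
        return {s for (s, t), m in self.edges.items() if t == site and m > 0}

    def pairs(self) -> list[tuple[str, str]]:
        """Edge list with multiplicity expanded, deterministically sorted."""
        out: list[tuple[str, str]] = []
        for (s, t), m in sorted(self.edges.items()):
            out.extend([(s, t)] * m)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MigrationGraph):
            return NotImplemented
        return (
            +self.edges == +other.edges  # drop zero entries
            and self.primary == other.primary
        )

    # -- export ------------------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(self.sites))
        for s, t in self.pairs():
            g.add_edge(s, t)
        return g

    def to_dot(self, name: str = "migrations") -> str:
        lines = [f"digraph {name} {{"]
        for site in sorted(self.sites):
            shape = "box" if site == self.primary else "ellipse"
            lines.append(f'  "{site}" [shape={shape}];')
        for s, t in self.pairs():
            lines.append(f'  "{s}" -> "{t}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        """One "source target" line per migration event (multiplicity kept)."""
        return "".join(f"{s}\t{t}\n" for s, t in self.pairs())

    @classmethod
    def from_tsv(
        cls,
        text: str,
        primary: str = PRIMARY_SITE,
        sites: Iterable[str] | None = None,
    ) -> "MigrationGraph":
        pairs = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            s, t = line.split()
            pairs.append((s, t))
        return cls.from_pairs(pairs, primary, sites)
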