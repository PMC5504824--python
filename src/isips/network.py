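"""Complex-centric PPI network assembly and neighbor-set queries.

The network is an undirected simple graph whose nodes are protein IDs.
Subunit nodes are flagged; every other node is, by construction, a
neighbor of at least one subunit because only subunit-touching records
survive the upstream filter.  Edges between two subunits are kept in
the graph but excluded from the external-interactor sets that drive the
similarity scores: intra-complex contacts carry no information about
which *outside* partners two subunits share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["ComplexDefinition", "PPINetwork", "build_network"]


@dataclass(frozen=True)
class ComplexDefinition:
    """The ordered set of subunit UniProt accessions of one complex."""

    subunits: tuple[str, ...]
    name: str = "complex"

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError("a complex needs at least one subunit")
        if len(set(self.subunits)) != len(self.subunits):
            raise ValueError("duplicate subunit identifiers in complex definition")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "ComplexDefinition":
        """Read one accession per line; '#' starts a comment."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"input list not found: {path}")
        subunits = []
        for line in path.read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                subunits.append(line)
        if not subunits:
            raise ValueError(f"input list {path} contains no subunit identifiers")
        return cls(tuple(subunits), name=name or path.stem)


@dataclass
class PPINetwork:
    """Undirected simple graph over protein IDs with flagged subunits."""

    graph: nx.Graph
    subunits: tuple[str, ...]

    @property
    def subunit_set(self) -> frozenset[str]:
        return frozenset(self.subunits)

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def external_interactors(self, members: Iterable[str]) -> set[str]:
        """Non-subunit proteins adjacent to at least one of ``members``."""
        members = set(members)
        unknown = members - self.subunit_set
        if unknown:
            raise KeyError(f"not subunits of the complex: {sorted(unknown)}")
        out: set[str] = set()
        for m in members:
            out.update(self.graph.neighbors(m))
        return out - self.subunit_set

    def subunit_neighbors(self, members: Iterable[str], exclude: Iterable[str] = ()) -> set[str]:
        """Subunits adjacent to ``members``, minus ``members`` and ``exclude``."""
        members = set(members)
        out: set[str] = set()
        for m in members:
            out.update(self.graph.neighbors(m))
        return (out & self.subunit_set) - members - set(exclude)

    def summary(self) -> tuple[int, int]:
        return self.graph.number_of_nodes(), self.graph.number_of_edges()

    def write_edge_list(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as handle:
            handle.write("protein_a\tprotein_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges()):
                handle.write(f"{a}\t{b}\n")

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for node in g.nodes:
            g.nodes[node]["is_subunit"] = node in self.subunit_set
        nx.write_graphml(g, path)


def build_network(
    pairs: Sequence[tuple[str, str]], complex_def: ComplexDefinition
) -> PPINetwork:
    """Assemble the graph from non-redundant unordered pairs.

    Subunits absent from every pair are kept as isolated nodes (with a
    logged warning) so that the clustering still places them in the
    output tree.
    """
    graph = nx.Graph()
    graph.add_nodes_from(complex_def.subunits)
    for a, b in pairs:
        if a == b:
            continue
        graph.add_edge(a, b)
    for su in complex_def.subunits:
        if graph.degree(su) == 0:
            logger.warning(
                "subunit %s has no interaction record; kept as isolated node", su
            )
    return PPINetwork(graph=graph, subunits=tuple(complex_def.subunits))
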