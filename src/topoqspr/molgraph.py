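"""Hydrogen-depleted molecular graphs and degree-based edge partitions.

A molecular graph here is the hydrogen-suppressed skeleton of a compound:
vertices are heavy atoms, and every bond — single, double or aromatic —
contributes exactly one edge. Element identity and bond order are not
modelled; every quantity downstream depends on connectivity only.

The central combinatorial object is the *edge partition*: the multiset of
unordered endpoint-degree pairs ``(d_u, d_v)`` over all edges, grouped with
counts. Any index of the form ``sum over edges of phi(d_u, d_v)`` can then be
evaluated class-by-class instead of edge-by-edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "MolecularGraph",
    "EdgePartition",
    "GraphValidationError",
    "EdgeListParseError",
    "from_edge_list",
    "degree",
    "edge_partition",
]


class GraphValidationError(ValueError):
    """Raised when a graph violates the molecular-graph invariants."""


class EdgeListParseError(ValueError):
    """Raised on a malformed edge-list document."""


@dataclass(frozen=True)
class MolecularGraph:
    """Simple undirected hydrogen-depleted skeleton of a molecule.

    Parameters
    ----------
    name
        Text label, typically the drug name.
    vertices
        Heavy-atom labels (opaque strings).
    edges
        Unordered pairs of vertex labels; one per bond.

    Invariants (enforced at construction): no self-loops, no duplicate
    edges, every edge endpoint declared, no isolated vertices.
    Disconnectedness is legal (the index formulas remain well-defined) but
    reported as a warning since a drug skeleton should be connected.
    """

    name: str
    vertices: frozenset[str]
    edges: frozenset[frozenset[str]]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        *,
        name: str = "",
        extra_vertices: Iterable[str] = (),
    ) -> "MolecularGraph":
        """Build and validate a graph from an iterable of endpoint pairs."""
        edge_set: set[frozenset[str]] = set()
        vertex_set: set[str] = set(str(v) for v in extra_vertices)
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise GraphValidationError(
                    f"{name or 'graph'}: self-loop on vertex {u!r}"
                )
            e = frozenset((u, v))
            if e in edge_set:
                raise GraphValidationError(
                    f"{name or 'graph'}: duplicate edge {u!r}-{v!r}"
                )
            edge_set.add(e)
            vertex_set.update((u, v))
        g = cls(name=name, vertices=frozenset(vertex_set), edges=frozenset(edge_set))
        g._validate()
        return g

    def _validate(self) -> None:
        incident = {v: 0 for v in self.vertices}
        for e in self.edges:
            for v in e:
                if v not in incident:
                    raise GraphValidationError(
                        f"{self.name or 'graph'}: edge endpoint {v!r} is not a declared vertex"
                    )
                incident[v] += 1
        isolated = sorted(v for v, k in incident.items() if k == 0)
        if isolated:
            raise GraphValidationError(
                f"{self.name or 'graph'}: isolated vertices {isolated} (every atom must bond)"
            )
        if self.vertices and not nx.is_connected(self.to_networkx()):
            warnings.warn(
                f"{self.name or 'graph'} is disconnected; indices remain well-defined",
                stacklevel=3,
            )

    # -- queries ---------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, v: str) -> int:
        """Number of edges incident to vertex ``v``."""
        if v not in self.vertices:
            raise GraphValidationError(f"unknown vertex {v!r}")
        return sum(1 for e in self.edges if v in e)

    def degrees(self) -> dict[str, int]:
        deg = {v: 0 for v in self.vertices}
        for e in self.edges:
            for v in e:
                deg[v] += 1
        return deg

    def edge_partition(self) -> "EdgePartition":
        """Tally edges by their unordered endpoint-degree pair."""
        deg = self.degrees()
        counts: dict[tuple[int, int], int] = {}
        for e in self.edges:
            u, v = tuple(e)
            key = (min(deg[u], deg[v]), max(deg[u], deg[v]))
            counts[key] = counts.get(key, 0) + 1
        return EdgePartition(counts=counts)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(self.vertices)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g


@dataclass(frozen=True)
class EdgePartition:
    """Multiset of endpoint-degree pairs, keys stored as (small, large).

    ``sum(counts.values())`` equals the edge count of the source graph.
    """

    counts: Mapping[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), c in self.counts.items():
            if not (1 <= a <= b):
                raise GraphValidationError(f"invalid partition key ({a}, {b})")
            if c < 0:
                raise GraphValidationError(f"negative count for class ({a}, {b})")

    @property
    def n_edges(self) -> int:
        return sum(self.counts.values())

    def items(self):
        return self.counts.items()


def from_edge_list(text: str, *, name: str = "") -> MolecularGraph:
    """Parse an edge-list document into a validated :class:`MolecularGraph`.

    Format: UTF-8 text, one edge per line as two whitespace-separated vertex
    labels. Lines starting with ``#`` are comments; blank lines are ignored.
    ``@vertex <label>`` lines declare a vertex explicitly (it must still end
    up with degree >= 1).
    """
    edges: list[tuple[str, str]] = []
    extra: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "@vertex":
            if len(parts) != 2:
                raise EdgeListParseError(
                    f"line {lineno}: '@vertex' takes exactly one label: {raw!r}"
                )
            extra.append(parts[1])
            continue
        if len(parts) != 2:
            raise EdgeListParseError(
                f"line {lineno}: expected two vertex labels, got {raw!r}"
            )
        edges.append((parts[0], parts[1]))
    return MolecularGraph.from_edges(edges, name=name, extra_vertices=extra)


def degree(g: MolecularGraph, v: str) -> int:
    """Degree of vertex ``v`` in ``g`` (thin wrapper)."""
    return g.degree(v)


def edge_partition(g: MolecularGraph) -> EdgePartition:
    """Degree-based edge partition of ``g`` (thin wrapper)."""
    return g.edge_partition()
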