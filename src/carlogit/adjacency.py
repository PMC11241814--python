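"""State adjacency graphs: the support of the Besag (iCAR) prior.

Areal units ("states") are the nodes; two units are neighbours when the
prior should smooth between them.  Graphs can be built synthetically
(grid, ring), from an explicit edge list, or from polygons by queen
contiguity (shared boundary point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np


class IslandError(ValueError):
    """A node with no neighbours, where the iCAR prior is undefined."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric neighbour structure over areal units.

    Attributes
    ----------
    nodes : tuple
        Unit labels in a fixed order; index in this tuple is the unit's
        integer code everywhere else in the package.
    edges : tuple of (label, label)
        Unordered unique neighbour pairs.
    """

    nodes: tuple
    edges: tuple
    _graph: nx.Graph = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-neighbour edge on node {a!r}")
            g.add_edge(a, b)
        object.__setattr__(self, "_graph", g)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def degrees(self) -> np.ndarray:
        """d_j, the neighbour count per unit (node order)."""
        return np.array([self._graph.degree[n] for n in self.nodes])

    @property
    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self._graph)

    def neighbours(self, node) -> set:
        return set(self._graph.neighbors(node))

    def index_of(self, node) -> int:
        return self.nodes.index(node)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense binary adjacency in node order."""
        return nx.to_numpy_array(self._graph, nodelist=self.nodes)

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian L = D - A; the iCAR precision is tau_s * L."""
        a = self.adjacency_matrix()
        return np.diag(a.sum(axis=1)) - a

    def edge_index_pairs(self) -> np.ndarray:
        """Unordered neighbour pairs as integer indices, shape (m, 2)."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        return np.array(
            sorted((min(idx[a], idx[b]), max(idx[a], idx[b])) for a, b in self.edges),
            dtype=int,
        ).reshape(-1, 2)

    def require_connected(self, context: str = "iCAR prior"):
        if not self.is_connected:
            isolates = [n for n in self.nodes if self._graph.degree[n] == 0]
            if isolates:
                raise IslandError(
                    f"node(s) {isolates} have no neighbours; {context} is undefined"
                )
            raise ValueError(f"graph is disconnected; {context} requires one component")


def _check_islands(graph: AdjacencyGraph):
    deg = graph.degrees
    if (deg == 0).any():
        bad = [graph.nodes[i] for i in np.flatnonzero(deg == 0)]
        raise IslandError(f"node(s) {bad} have no neighbours (island)")


def grid_adjacency(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-contiguity grid of rows x cols units, labelled 0..n-1 row-major."""
    if rows * cols < 2:
        raise ValueError("grid must have at least 2 nodes")
    g = nx.grid_2d_graph(rows, cols)
    order = sorted(g.nodes())
    relabel = {rc: i for i, rc in enumerate(order)}
    edges = tuple(sorted((relabel[a], relabel[b]) if relabel[a] < relabel[b]
                         else (relabel[b], relabel[a]) for a, b in g.edges()))
    out = AdjacencyGraph(nodes=tuple(range(rows * cols)), edges=edges)
    _check_islands(out)
    return out


def ring_adjacency(n: int) -> AdjacencyGraph:
    """Cycle of n >= 3 units labelled 0..n-1."""
    if n < 3:
        raise ValueError("ring needs at least 3 nodes")
    edges = tuple((i, (i + 1) % n) if i < (i + 1) % n else ((i + 1) % n, i)
                  for i in range(n))
    return AdjacencyGraph(nodes=tuple(range(n)), edges=tuple(sorted(edges)))


def from_edge_list(edges, nodes=None) -> AdjacencyGraph:
    """Build a graph from (a, b) pairs; duplicates are dropped with a warning.

    ``nodes`` fixes the node order (and may include extra isolated nodes,
    which raise IslandError); otherwise nodes are the sorted endpoint set.
    """
    seen = set()
    uniq = []
    dups = 0
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-neighbour edge on node {a!r}")
        try:
            key = (a, b) if a <= b else (b, a)
        except TypeError:  # mixed label types
            key = (a, b) if str(a) <= str(b) else (b, a)
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        uniq.append(key)
    if dups:
        warnings.warn(f"{dups} duplicated edge(s) removed", stacklevel=2)
    if nodes is None:
        found = {n for e in uniq for n in e}
        try:
            nodes = tuple(sorted(found))
        except TypeError:  # mixed label types
            nodes = tuple(sorted(found, key=str))
    graph = AdjacencyGraph(nodes=tuple(nodes), edges=tuple(uniq))
    _check_islands(graph)
    return graph


def make_adjacency(topology: str, **params) -> AdjacencyGraph:
    """Dispatch constructor: topology in {'grid', 'ring', 'from_edge_list'}."""
    if topology == "grid":
        return grid_adjacency(params["rows"], params["cols"])
    if topology == "ring":
        return ring_adjacency(params["n"])
    if topology == "from_edge_list":
        return from_edge_list(params["edges"], params.get("nodes"))
    raise ValueError(f"unknown topology {topology!r}")


def queen_adjacency(polygons: dict) -> AdjacencyGraph:
    """Queen contiguity: units are neighbours if their boundaries share
    at least one point (a single shared corner qualifies).

    Parameters
    ----------
    polygons : mapping of unit label -> shapely geometry
    """
    from shapely.validation import explain_validity

    labels = list(polygons)
    for lab in labels:
        geom = polygons[lab]
        if not geom.is_valid:
            raise ValueError(
                f"invalid geometry for polygon {lab!r}: {explain_validity(geom)}"
            )
    edges = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if polygons[a].intersects(polygons[b]):
                edges.append((a, b))
    graph = AdjacencyGraph(nodes=tuple(labels), edges=tuple(edges))
    _check_islands(graph)
    return graph


def write_edge_list(graph: AdjacencyGraph, path):
    """Two-column whitespace-separated edge list; header line with '#'."""
    with open(path, "w") as fh:
        fh.write("# node_a node_b\n")
        for a, b in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{a} {b}\n")


def read_edge_list(path) -> AdjacencyGraph:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected two columns, got {line!r}")
            a, b = parts
            edges.append((int(a) if a.isdigit() else a, int(b) if b.isdigit() else b))
    return from_edge_list(edges)
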