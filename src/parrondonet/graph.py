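"""Population graph container.

The agents of the capital-exchange games live on the nodes of an undirected
simple graph.  :class:`NetworkGraph` is a thin validated wrapper around a
:class:`networkx.Graph` with contiguous 0-based integer node ids; it exposes
the CSR arrays the simulation kernels consume.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["NetworkGraph", "read_edgelist", "write_edgelist"]


@dataclass
class NetworkGraph:
    """Undirected simple graph with nodes ``0 .. n-1``.

    Invariants enforced by :meth:`validate`: symmetric adjacency, no
    self-loops, no parallel edges (guaranteed by the ``networkx.Graph``
    representation), and minimum degree 1 — every agent needs at least one
    neighbor to act as the object of the pairwise game.
    """

    nx_graph: nx.Graph
    _csr: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_edges(cls, n: int, edges) -> "NetworkGraph":
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        return cls(g)

    # -- properties ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.nx_graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.nx_graph.number_of_edges()

    @property
    def degrees(self) -> np.ndarray:
        return np.array([d for _, d in sorted(self.nx_graph.degree)], dtype=np.int64)

    def neighbors(self, i: int) -> set[int]:
        return set(self.nx_graph.neighbors(i))

    def is_connected(self) -> bool:
        return nx.is_connected(self.nx_graph)

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency in compressed sparse row form ``(indptr, indices)``.

        Neighbor lists are sorted so the kernel's neighbor draw order is a
        pure function of the graph, not of construction history.
        """
        if self._csr is None:
            n = self.n
            indptr = np.zeros(n + 1, dtype=np.int64)
            nbr_lists = []
            for i in range(n):
                nbrs = sorted(self.nx_graph.neighbors(i))
                nbr_lists.append(nbrs)
                indptr[i + 1] = indptr[i] + len(nbrs)
            indices = np.fromiter(
                (j for nbrs in nbr_lists for j in nbrs),
                dtype=np.int64,
                count=int(indptr[-1]),
            )
            self._csr = (indptr, indices)
        return self._csr

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        g = self.nx_graph
        n = g.number_of_nodes()
        if n < 1:
            raise ValueError("graph must have at least one node")
        if set(g.nodes) != set(range(n)):
            raise ValueError("node ids must be contiguous integers 0..n-1")
        if any(g.has_edge(i, i) for i in g.nodes):
            raise ValueError("self-loops are not allowed")
        degs = dict(g.degree)
        isolated = [i for i, d in degs.items() if d == 0]
        if isolated:
            raise ValueError(
                f"every node needs a neighbor; degree-0 nodes: {isolated[:5]}"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, NetworkGraph):
            return NotImplemented
        return self.n == other.n and set(
            map(frozenset, self.nx_graph.edges)
        ) == set(map(frozenset, other.nx_graph.edges))


def write_edgelist(graph: NetworkGraph, path) -> None:
    """Write one edge per line (two 0-based node ids); ``# nodes=N`` header."""
    with open(path, "w") as fh:
        fh.write(f"# nodes={graph.n}\n")
        for u, v in sorted(map(sorted, graph.nx_graph.edges)):
            fh.write(f"{u} {v}\n")


def read_edgelist(path) -> NetworkGraph:
    """Read an edge-list file and validate all graph invariants."""
    n_declared = None
    edges = []
    seen: set[frozenset] = set()
    if isinstance(path, io.IOBase):
        lines = path.readlines()
    else:
        with open(path) as fh:
            lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.startswith("nodes="):
                n_declared = int(stripped.split("=", 1)[1])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected two node ids, got {line!r}")
        u, v = int(parts[0]), int(parts[1])
        if u == v:
            raise ValueError(f"line {lineno}: self-loop {u}-{v}")
        key = frozenset((u, v))
        if key in seen:
            raise ValueError(f"line {lineno}: duplicate edge {u}-{v}")
        seen.add(key)
        edges.append((u, v))
    if n_declared is None:
        n_declared = 1 + max(max(e) for e in edges)
    return NetworkGraph.from_edges(n_declared, edges)
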