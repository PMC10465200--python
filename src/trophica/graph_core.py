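"""Directed-graph container, standard-format I/O and connectivity primitives.

The central object is :class:`DirectedNetwork`, a simple (no self-loops, no
multi-edges) directed graph stored as an edge set with a cached sparse
adjacency matrix.  The adjacency convention is ``A[i, j] = 1`` iff there is an
edge ``i -> j``, so rows index sources and columns index targets.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedNetwork",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "degrees",
    "out_component_sizes",
    "strongly_connected_components",
    "weakly_connected_components",
]


class DirectedNetwork:
    """A simple directed graph on nodes ``0 .. n_nodes - 1``.

    Parameters
    ----------
    n_nodes:
        Number of nodes (positive).
    edges:
        Iterable of ordered pairs ``(i, j)`` meaning an edge ``i -> j``.
        Self-loops are rejected; duplicates are collapsed silently (loaders
        that want to warn should deduplicate before construction).
    node_labels:
        Optional sequence of string labels, one per node; preserved by the
        edge-list and GraphML writers.
    """

    __slots__ = ("n_nodes", "edges", "node_labels", "_adjacency")

    def __init__(
        self,
        n_nodes: int,
        edges: Iterable[tuple[int, int]],
        node_labels: Iterable[str] | None = None,
    ):
        n_nodes = int(n_nodes)
        if n_nodes < 1:
            raise ValueError("n_nodes must be a positive integer")
        edge_set = set()
        for e in edges:
            i, j = int(e[0]), int(e[1])
            if i == j:
                raise ValueError(f"self-loop ({i}, {i}) is not allowed")
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise ValueError(f"edge ({i}, {j}) has endpoint outside [0, {n_nodes})")
            edge_set.add((i, j))
        self.n_nodes = n_nodes
        self.edges = frozenset(edge_set)
        if node_labels is not None:
            node_labels = tuple(str(x) for x in node_labels)
            if len(node_labels) != n_nodes:
                raise ValueError("node_labels length must equal n_nodes")
        self.node_labels = node_labels
        self._adjacency = None

    # -- views -------------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> np.ndarray:
        """Edges as an (m, 2) int array in lexicographic order (deterministic)."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Cached sparse adjacency with ``A[i, j] = 1`` iff ``(i, j)`` is an edge."""
        if self._adjacency is None:
            e = self.sorted_edges()
            self._adjacency = sp.csr_matrix(
                (np.ones(len(e)), (e[:, 0], e[:, 1])),
                shape=(self.n_nodes, self.n_nodes),
            )
        return self._adjacency

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        if self.node_labels is not None:
            nx.set_node_attributes(
                g, dict(enumerate(self.node_labels)), name="label"
            )
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedNetwork":
        """Convert a networkx digraph; nodes are relabelled ``0..n-1`` in
        insertion order and original names kept as labels.  Self-loops are
        dropped with a logged warning."""
        nodes = list(g.nodes())
        index = {u: k for k, u in enumerate(nodes)}
        edges = []
        n_loops = 0
        for u, v in g.edges():
            if u == v:
                n_loops += 1
                continue
            edges.append((index[u], index[v]))
        if n_loops:
            logger.warning("dropped %d self-loop(s) during conversion", n_loops)
        return cls(len(nodes), edges, node_labels=[str(u) for u in nodes])

    # -- dunders -----------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return self.n_nodes == other.n_nodes and self.edges == other.edges

    def __hash__(self):
        return hash((self.n_nodes, self.edges))

    def __repr__(self):
        return f"DirectedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# -- I/O -------------------------------------------------------------------


def read_edge_list(path, delimiter: str | None = None) -> DirectedNetwork:
    """Read a two-column edge list (``source<delim>target`` per line).

    Labels may be arbitrary strings and are mapped to 0-based indices in
    first-appearance order.  Lines starting with ``#`` are ignored.  Duplicate
    edges are collapsed and self-loops dropped, each with a logged warning.

    Parameters
    ----------
    path:
        File to read.
    delimiter:
        Column separator; ``None`` splits on any whitespace.
    """
    index: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    n_dup = n_loop = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            idx = []
            for token in parts:
                if token not in index:
                    index[token] = len(index)
                idx.append(index[token])
            i, j = idx
            if i == j:
                n_loop += 1
                continue
            if (i, j) in seen:
                n_dup += 1
                continue
            seen.add((i, j))
            edges.append((i, j))
    if not index:
        raise ValueError(f"{path}: empty edge list")
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dup)
    if n_loop:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loop)
    labels = [None] * len(index)
    for name, k in index.items():
        labels[k] = name
    return DirectedNetwork(len(index), edges, node_labels=labels)


def write_edge_list(net: DirectedNetwork, path, delimiter: str = "\t") -> None:
    """Write an edge list mirroring :func:`read_edge_list` (labels if present)."""
    labels = net.node_labels or [str(k) for k in range(net.n_nodes)]
    with open(path, "w") as fh:
        for i, j in net.sorted_edges():
            fh.write(f"{labels[i]}{delimiter}{labels[j]}\n")


def read_graphml(path) -> DirectedNetwork:
    """Load a directed GraphML file (e.g. from a real-network deposit)."""
    g = nx.read_graphml(path)
    if not g.is_directed():
        raise ValueError(f"{path}: expected a directed graph")
    g = nx.DiGraph(g)  # collapse potential multi-edges
    net = DirectedNetwork.from_networkx(g)
    n_weak = nx.number_weakly_connected_components(g)
    if n_weak > 1:
        logger.warning("%s: graph has %d weakly connected components", path, n_weak)
    return net


def write_graphml(net: DirectedNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)


# -- degrees and connectivity ---------------------------------------------


def degrees(net: DirectedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(in_degree, out_degree)`` integer vectors."""
    a = net.adjacency
    in_deg = np.asarray(a.sum(axis=0)).ravel().astype(np.int64)
    out_deg = np.asarray(a.sum(axis=1)).ravel().astype(np.int64)
    return in_deg, out_deg


def out_component_sizes(net: DirectedNetwork) -> np.ndarray:
    """Number of nodes reachable from each node by directed paths.

    The node itself is excluded, so values lie in ``[0, n_nodes - 1]`` and a
    node in a strongly connected spanning graph scores ``n_nodes - 1``.
    """
    g = net.to_networkx()
    # Condense to the SCC quotient DAG so reachability is computed once per
    # component instead of once per node.
    cond = nx.condensation(g)
    order = list(nx.topological_sort(cond))
    n_comp = cond.number_of_nodes()
    comp_sizes = np.array([len(cond.nodes[c]["members"]) for c in range(n_comp)])
    reach = [None] * n_comp  # set of reachable SCC ids, inclusive of self
    for c in reversed(order):
        r = {c}
        for succ in cond.successors(c):
            r |= reach[succ]
        reach[c] = r
    comp_reach = np.array([sum(comp_sizes[list(r)]) for r in reach])
    sizes = np.empty(net.n_nodes, dtype=np.int64)
    for c in range(n_comp):
        for node in cond.nodes[c]["members"]:
            sizes[node] = comp_reach[c] - 1
    return sizes


def strongly_connected_components(net: DirectedNetwork) -> list[set[int]]:
    return [set(c) for c in nx.strongly_connected_components(net.to_networkx())]


def weakly_connected_components(net: DirectedNetwork) -> list[set[int]]:
    return [set(c) for c in nx.weakly_connected_components(net.to_networkx())]
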