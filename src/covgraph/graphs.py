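"""Benchmark graph topologies for Gaussian graphical model studies.

Four generators produce the binary concentration-graph structures commonly
used to benchmark network-reconstruction methods: a chain (tridiagonal
adjacency), a cluster graph (disjoint Erdos-Renyi blocks), a scale-free tree
(Barabasi-Albert preferential attachment with one edge per new node), and a
hub graph (disjoint stars).

All graphs are undirected and are represented by a symmetric, zero-diagonal
adjacency matrix wrapped in :class:`WeightedGraph`.  Generators return binary
(0/1) adjacencies; weights are attached downstream when a positive-definite
model is built from the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

__all__ = [
    "WeightedGraph",
    "GraphStats",
    "make_chain_graph",
    "make_cluster_graph",
    "make_scale_free_graph",
    "make_hub_graph",
    "graph_stats",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
]


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected weighted graph stored as a symmetric adjacency matrix.

    The edge set is the off-diagonal nonzero pattern: ``(i, j)`` with
    ``i < j`` is an edge iff ``adjacency[i, j] != 0``, and its weight is
    that entry.  Node indices are 0-based internally; I/O helpers emit
    1-based labels.
    """

    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.allclose(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        object.__setattr__(self, "adjacency", adj)

    @property
    def p(self) -> int:
        """Number of nodes."""
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of edges (unordered pairs with nonzero weight)."""
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    @property
    def edge_mask(self) -> np.ndarray:
        """Boolean vector over the upper-triangular pair order."""
        iu = np.triu_indices(self.p, 1)
        return self.adjacency[iu] != 0

    def edges(self) -> list[tuple[int, int, float]]:
        """Edge list as ``(i, j, weight)`` with 0-based ``i < j``."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return [(int(a), int(b), float(self.adjacency[a, b])) for a, b in zip(i, j)]

    def is_binary(self) -> bool:
        vals = np.unique(self.adjacency)
        return np.all(np.isin(vals, (0.0, 1.0)))

    def n_components(self) -> int:
        n, _ = connected_components((self.adjacency != 0).astype(int), directed=False)
        return int(n)

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


@dataclass(frozen=True)
class GraphStats:
    """Degree summary of a graph: per-node degrees, max degree, edge count."""

    degrees: np.ndarray
    k_max: int
    n_edges: int


def make_chain_graph(p: int) -> WeightedGraph:
    """Chain graph on ``p`` nodes: tridiagonal adjacency with ``p - 1`` edges.

    Parameters
    ----------
    p : int
        Number of nodes, at least 2.
    """
    if p < 2:
        raise ValueError(f"chain graph needs p >= 2, got {p}")
    adj = np.zeros((p, p))
    idx = np.arange(p - 1)
    adj[idx, idx + 1] = 1.0
    adj[idx + 1, idx] = 1.0
    return WeightedGraph(adj)


def make_cluster_graph(
    p: int,
    l: int,
    edge_prob: float,
    seed: int | np.random.Generator | None = None,
) -> WeightedGraph:
    """Cluster graph: ``l`` disjoint Erdos-Renyi blocks of ``p / l`` nodes.

    Within each block any pair is connected independently with probability
    ``edge_prob``; there are no between-block edges, so the expected edge
    count is ``p * (p / l - 1) * edge_prob / 2``.

    Parameters
    ----------
    p : int
        Number of nodes; must be divisible by ``l``.
    l : int
        Number of blocks.
    edge_prob : float
        Within-block edge probability in ``(0, 1]``.  Zero is rejected: a
        cluster graph with no edges is degenerate for any benchmark use.
    seed : int, Generator, optional
        Source of randomness.
    """
    if p % l != 0:
        raise ValueError(f"number of clusters l={l} must divide p={p}")
    if not 0 < edge_prob <= 1:
        raise ValueError(f"edge_prob must be in (0, 1], got {edge_prob}")
    rng = np.random.default_rng(seed)
    b = p // l
    adj = np.zeros((p, p))
    for k in range(l):
        lo = k * b
        block = np.triu((rng.random((b, b)) < edge_prob).astype(float), 1)
        adj[lo : lo + b, lo : lo + b] = block + block.T
    return WeightedGraph(adj)


def make_scale_free_graph(
    p: int,
    seed: int | np.random.Generator | None = None,
    m: int = 1,
) -> WeightedGraph:
    """Scale-free graph by Barabasi-Albert preferential attachment.

    New nodes attach to an existing node ``i`` with probability proportional
    to its degree, ``P(k_i) = k_i / sum_j k_j``.  With the default ``m = 1``
    the result is a connected tree with exactly ``p - 1`` edges, whose degree
    distribution follows a power law ``P(k) ~ k^-gamma``.
    """
    if p < 2:
        raise ValueError(f"scale-free graph needs p >= 2, got {p}")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(p, m, seed=rng)
    adj = nx.to_numpy_array(g)
    adj[adj != 0] = 1.0
    return WeightedGraph(adj)


def make_hub_graph(p: int, l: int) -> WeightedGraph:
    """Hub graph: ``l`` disjoint stars over blocks of ``p / l`` nodes.

    The first node of each block is the hub, connected to the remaining
    ``p / l - 1`` block members; leaves have degree 1.  Total edge count is
    ``p - l``.
    """
    if p % l != 0:
        raise ValueError(f"number of hubs l={l} must divide p={p}")
    b = p // l
    adj = np.zeros((p, p))
    for k in range(l):
        h = k * b
        adj[h, h + 1 : h + b] = 1.0
        adj[h + 1 : h + b, h] = 1.0
    return WeightedGraph(adj)


def graph_stats(g: WeightedGraph) -> GraphStats:
    """Degrees, maximum degree and edge count of the nonzero pattern."""
    pattern = (g.adjacency != 0).astype(int)
    degrees = pattern.sum(axis=0)
    return GraphStats(
        degrees=degrees,
        k_max=int(degrees.max(initial=0)),
        n_edges=int(pattern.sum() // 2),
    )


# ---------------------------------------------------------------------------
# Plain-text I/O: TSV edge lists (1-based, i < j) and dense CSV adjacencies.

def write_edge_list(g: WeightedGraph, path, header: bool = False) -> None:
    rows = [(i + 1, j + 1, w) for i, j, w in g.edges()]
    df = pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])
    df.to_csv(path, sep="\t", index=False, header=header)


def read_edge_list(path, p: int | None = None, header: bool = False) -> WeightedGraph:
    df = pd.read_csv(
        path, sep="\t", header=0 if header else None,
        names=["node_i", "node_j", "weight"],
    )
    i = df["node_i"].to_numpy(dtype=int) - 1
    j = df["node_j"].to_numpy(dtype=int) - 1
    w = df["weight"].to_numpy(dtype=float)
    if p is None:
        p = int(max(i.max(initial=-1), j.max(initial=-1)) + 1)
    adj = np.zeros((p, p))
    adj[i, j] = w
    adj[j, i] = w
    return WeightedGraph(adj)


def write_adjacency(g: WeightedGraph, path) -> None:
    np.savetxt(path, g.adjacency, delimiter=",")


def read_adjacency(path) -> WeightedGraph:
    return WeightedGraph(np.loadtxt(path, delimiter=",", ndmin=2))
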