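"""Graph and attractiveness construction.

Containers for the two layers of the embedding model — a large network A
(only its degree sequence enters the analytics, the full edge list enters
the simulator) and a small location network B (full adjacency required) —
plus the per-node attractiveness weights on B, file I/O for plain-text edge
lists and node-attribute tables, and the random-graph generators used as
experimental fixtures (Erdős–Rényi, Barabási–Albert, and a Voronoi/Delaunay
spatial-adjacency network on the unit square).

Node indices are 0-based and contiguous everywhere; any label remapping
happens at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "UndirectedGraph",
    "AttractivenessVector",
    "DegreeMoments",
    "read_edge_list",
    "write_edge_list",
    "read_attractiveness",
    "write_attractiveness",
    "generate_er",
    "generate_ba",
    "generate_voronoi_adjacency",
    "sample_attractiveness",
    "degree_moments",
]

logger = logging.getLogger(__name__)


class UndirectedGraph:
    """Simple undirected, unweighted graph with 0-based contiguous nodes.

    Edges are stored as a canonical ``(m, 2)`` integer array with
    ``u < v`` on every row, sorted lexicographically; self-loops and
    multi-edges are rejected at construction.

    Parameters
    ----------
    n_nodes : int
        Number of nodes (may exceed the largest endpoint, allowing
        isolated nodes).
    edges : array-like of shape (m, 2)
        Unordered node-index pairs.
    """

    __slots__ = ("n_nodes", "edges", "_adj_indptr", "_adj_indices")

    def __init__(self, n_nodes: int, edges) -> None:
        n_nodes = int(n_nodes)
        if n_nodes < 1:
            raise ValueError(f"n_nodes must be positive, got {n_nodes}")
        e = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if e.size:
            if (e < 0).any():
                raise ValueError("negative node index in edge list")
            if (e >= n_nodes).any():
                bad = e[(e >= n_nodes).any(axis=1)][0]
                raise ValueError(
                    f"edge {tuple(bad)} references a node >= n_nodes={n_nodes}"
                )
            if (e[:, 0] == e[:, 1]).any():
                bad = e[e[:, 0] == e[:, 1]][0]
                raise ValueError(f"self-loop at node {bad[0]} is not allowed")
            e = np.sort(e, axis=1)
            e = np.unique(e, axis=0)
        self.n_nodes = n_nodes
        self.edges = e
        self._adj_indptr = None
        self._adj_indices = None

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        """Degree of every node, length ``n_nodes``."""
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    def _build_adjacency(self) -> None:
        deg = self.degrees()
        indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        np.cumsum(deg, out=indptr[1:])
        indices = np.empty(2 * self.n_edges, dtype=np.int64)
        fill = indptr[:-1].copy()
        for u, v in self.edges:
            indices[fill[u]] = v
            fill[u] += 1
            indices[fill[v]] = u
            fill[v] += 1
        self._adj_indptr = indptr
        self._adj_indices = indices

    def neighbors(self, node: int) -> np.ndarray:
        """Neighbor indices of ``node`` (view into a CSR-style buffer)."""
        if self._adj_indptr is None:
            self._build_adjacency()
        return self._adj_indices[self._adj_indptr[node]:self._adj_indptr[node + 1]]

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        if self.n_edges:
            a[self.edges[:, 0], self.edges[:, 1]] = 1.0
            a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a

    def is_connected(self) -> bool:
        if self.n_nodes == 1:
            return True
        if self._adj_indptr is None:
            self._build_adjacency()
        seen = np.zeros(self.n_nodes, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            u = stack.pop()
            for v in self.neighbors(u):
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        return bool(seen.all())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "UndirectedGraph":
        nodes = sorted(g.nodes())
        if nodes != list(range(len(nodes))):
            relabel = {n: i for i, n in enumerate(nodes)}
            g = nx.relabel_nodes(g, relabel)
        return cls(g.number_of_nodes(), np.array(list(g.edges()), dtype=np.int64).reshape(-1, 2))

    def __eq__(self, other) -> bool:
        if not isinstance(other, UndirectedGraph):
            return NotImplemented
        return self.n_nodes == other.n_nodes and np.array_equal(self.edges, other.edges)

    def __repr__(self) -> str:
        return f"UndirectedGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class AttractivenessVector:
    """Normalized per-node attractiveness weights f on network B.

    Entries are strictly positive and sum to one, so f_i is both the
    probability that node i receives a source node directly and its pull
    on passing walkers. Arbitrary positive weights (e.g. raw city
    populations) are accepted and normalized at construction.
    """

    f: np.ndarray = field()

    def __init__(self, weights) -> None:
        w = np.asarray(weights, dtype=float).ravel()
        if w.size < 1:
            raise ValueError("attractiveness vector must be non-empty")
        if not np.all(w > 0):
            raise ValueError("all attractiveness weights must be strictly positive")
        if not np.all(np.isfinite(w)):
            raise ValueError("attractiveness weights must be finite")
        object.__setattr__(self, "f", w / w.sum())

    def __len__(self) -> int:
        return self.f.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.f, dtype=dtype)


@dataclass(frozen=True)
class DegreeMoments:
    """First two moments of a degree distribution plus the node count."""

    mean_k: float
    mean_k2: float
    n_nodes: int

    def __post_init__(self):
        if self.mean_k < 0:
            raise ValueError("mean degree must be nonnegative")
        if self.mean_k2 < self.mean_k**2 - 1e-9:
            raise ValueError("mean_k2 < mean_k^2 violates Jensen's inequality")


def read_edge_list(path, n_nodes: int | None = None) -> UndirectedGraph:
    """Read a plain-text edge list: two whitespace-separated integers per
    line, ``#`` comments ignored, ``(u, v)`` and ``(v, u)`` identified,
    duplicate lines collapsed.
    """
    edges = []
    max_node = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two integers, got {line!r}")
            u, v = int(parts[0]), int(parts[1])
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u}-{v} is not allowed")
            if n_nodes is not None and (u >= n_nodes or v >= n_nodes):
                raise ValueError(
                    f"{path}:{lineno}: endpoint {max(u, v)} >= n_nodes={n_nodes}"
                )
            edges.append((u, v))
            max_node = max(max_node, u, v)
    n = n_nodes if n_nodes is not None else max_node + 1
    if n < 1:
        raise ValueError(f"{path}: empty edge list and no n_nodes given")
    return UndirectedGraph(n, np.array(edges, dtype=np.int64).reshape(-1, 2))


def write_edge_list(g: UndirectedGraph, path) -> None:
    """Write ``g`` so that :func:`read_edge_list` round-trips exactly."""
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={g.n_nodes} n_edges={g.n_edges}\n")
        for u, v in g.edges:
            fh.write(f"{u} {v}\n")


def read_attractiveness(path) -> AttractivenessVector:
    """Read a ``node,f[,x,y]`` CSV node-attribute table."""
    df = pd.read_csv(path)
    df = df.sort_values("node")
    if not np.array_equal(df["node"].to_numpy(), np.arange(len(df))):
        raise ValueError(f"{path}: node column must be 0..n-1 contiguous")
    return AttractivenessVector(df["f"].to_numpy())


def write_attractiveness(f: AttractivenessVector, path, positions=None) -> None:
    data = {"node": np.arange(len(f)), "f": f.f}
    if positions is not None:
        pos = np.asarray(positions, dtype=float)
        data["x"] = pos[:, 0]
        data["y"] = pos[:, 1]
    pd.DataFrame(data).to_csv(path, index=False)


def generate_er(n: int, p: float, seed) -> UndirectedGraph:
    """Erdős–Rényi G(n, p): each unordered pair is an edge independently
    with probability p."""
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    g = nx.fast_gnp_random_graph(n, p, seed=_nx_seed(seed))
    return UndirectedGraph(n, np.array(list(g.edges()), dtype=np.int64).reshape(-1, 2))


def generate_ba(n: int, m: int, seed) -> UndirectedGraph:
    """Barabási–Albert preferential attachment; with m=1 the result is a
    tree with n-1 edges."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not 1 <= m < n:
        raise ValueError(f"need 1 <= m < n, got m={m}, n={n}")
    g = nx.barabasi_albert_graph(n, m, seed=_nx_seed(seed))
    return UndirectedGraph(n, np.array(list(g.edges()), dtype=np.int64).reshape(-1, 2))


def generate_voronoi_adjacency(n: int, seed, max_retries: int = 10):
    """Spatial-adjacency network of n points uniform on the unit square.

    Two nodes are linked iff their Voronoi cells share a boundary
    segment, realized as Delaunay neighborship (open boundaries, no
    periodic wrapping). Degenerate point sets are re-sampled.

    Returns
    -------
    (UndirectedGraph, ndarray of shape (n, 2))
        The adjacency graph and the sampled point positions.
    """
    from scipy.spatial import Delaunay, QhullError

    if n < 3:
        raise ValueError(f"need n >= 3 points for a tessellation, got {n}")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        pts = rng.uniform(0.0, 1.0, size=(n, 2))
        try:
            tri = Delaunay(pts)
        except QhullError:
            logger.warning("degenerate point set on attempt %d; re-sampling", attempt + 1)
            continue
        edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                u, v = int(simplex[a]), int(simplex[(a + 1) % 3])
                edges.add((min(u, v), max(u, v)))
        g = UndirectedGraph(n, np.array(sorted(edges), dtype=np.int64))
        if not g.is_connected():  # cannot happen for a valid triangulation
            logger.warning("disconnected triangulation on attempt %d; re-sampling", attempt + 1)
            continue
        return g, pts
    raise RuntimeError(f"failed to build a Voronoi adjacency in {max_retries} attempts")


def sample_attractiveness(n: int, low: float = 1.0, high: float = 100.0, seed=None) -> AttractivenessVector:
    """Raw weights i.i.d. Uniform(low, high), then rescaled to sum to 1."""
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    rng = np.random.default_rng(seed)
    return AttractivenessVector(rng.uniform(low, high, size=n))


def degree_moments(g: UndirectedGraph) -> DegreeMoments:
    """Exact first and second moments of the degree sequence."""
    k = g.degrees().astype(float)
    return DegreeMoments(float(k.mean()), float((k**2).mean()), g.n_nodes)


def _nx_seed(seed):
    """networkx accepts ints or numpy Generators; normalize anything else."""
    if seed is None or isinstance(seed, (int, np.integer, np.random.Generator)):
        return seed if not isinstance(seed, np.integer) else int(seed)
    return np.random.default_rng(seed)
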