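"""Linear-algebra layer for the location network B.

Three objects drive every closed-form prediction of the embedding model:

* the column-stochastic transition matrix ``C`` of the attractiveness-
  weighted random walk on B, with hop probability
  ``C[i, j] = f_i B_ij / sum_l f_l B_lj`` (column j -> row i);
* the discounted walk propagator ``Omega(q) = sum_{r>=1} (1-q)^r C^r``,
  which encodes where a walk with per-step stopping probability q halts
  after at least one hop (computed by a dense linear solve, never by
  series truncation in production code);
* the stationary distribution ``v0`` of C (eigenvalue-1 eigenvector,
  L1-normalized), defining the fully delocalized q -> 0 limit.

B is small by the model's premise (N_A >> N_B), so dense algebra is used
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .location_networks import AttractivenessVector, UndirectedGraph

__all__ = [
    "TransitionMatrix",
    "WalkPropagator",
    "StationaryDistribution",
    "build_transition_matrix",
    "walk_propagator",
    "walk_propagator_series",
    "stationary_distribution",
    "halting_distribution",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic hop kernel C of the weighted walk on B."""

    C: np.ndarray

    @property
    def n(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class WalkPropagator:
    """Omega(q) = sum_{r>=1} (1-q)^r C^r; every column sums to (1-q)/q."""

    omega: np.ndarray
    q: float


@dataclass(frozen=True)
class StationaryDistribution:
    """L1-normalized eigenvalue-1 eigenvector v0 of C."""

    v0: np.ndarray


def build_transition_matrix(B: UndirectedGraph, f: AttractivenessVector) -> TransitionMatrix:
    """Exact formula C_ij = f_i B_ij / sum_k f_k B_kj.

    Raises if any B-node is isolated (its column normalizer vanishes).
    """
    if len(f) != B.n_nodes:
        raise ValueError(f"f has length {len(f)} but B has {B.n_nodes} nodes")
    deg = B.degrees()
    isolated = np.flatnonzero(deg == 0)
    if isolated.size:
        raise ValueError(f"isolated node(s) in B: {isolated.tolist()}")
    adj = B.adjacency()
    weighted = f.f[:, None] * adj  # entry (i, j) = f_i B_ij
    col = weighted.sum(axis=0)
    return TransitionMatrix(weighted / col[None, :])


def walk_propagator(C: TransitionMatrix, q: float) -> WalkPropagator:
    """Closed-form Omega(q) = (1-q) C (I - (1-q) C)^{-1} via linear solve.

    The geometric series converges because the spectral radius of C is 1
    and the discount 1-q < 1. At q=1 the propagator is the zero matrix.
    """
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    n = C.n
    a = 1.0 - q
    if a == 0.0:
        return WalkPropagator(np.zeros((n, n)), q)
    omega = scipy.linalg.solve(np.eye(n) - a * C.C, a * C.C)
    return WalkPropagator(omega, q)


def walk_propagator_series(C: TransitionMatrix, q: float, r_max: int) -> np.ndarray:
    """Truncated series sum_{r=1}^{r_max} (1-q)^r C^r (test oracle only)."""
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    acc = np.zeros_like(C.C)
    term = np.eye(C.n)
    for _ in range(r_max):
        term = (1.0 - q) * (C.C @ term)
        acc += term
    return acc


def stationary_distribution(C: TransitionMatrix, graph: UndirectedGraph | None = None) -> StationaryDistribution:
    """Eigenvalue-1 eigenvector of C, L1-normalized to a probability vector.

    Unique by Perron-Frobenius when C is irreducible (B connected); a
    disconnected B is rejected with its component structure reported.
    Bipartite B is fine: only the stationary vector is used, not chain
    convergence, so no aperiodicity requirement is imposed.
    """
    if graph is not None and not graph.is_connected():
        import networkx as nx

        comps = [sorted(c) for c in nx.connected_components(graph.to_networkx())]
        raise ValueError(
            f"B is disconnected ({len(comps)} components: {comps}); "
            "the stationary distribution is not unique"
        )
    vals, vecs = scipy.linalg.eig(C.C)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    if abs(vals[idx] - 1.0) > 1e-8:
        raise ValueError("no eigenvalue-1 eigenvector found; is C column-stochastic?")
    v = np.real(vecs[:, idx])
    v = v * np.sign(v.sum())
    if (v < -1e-10).any():
        # eigensolver degeneracy; fall back to power iteration on (I+C)/2
        v = np.full(C.n, 1.0 / C.n)
        m = 0.5 * (np.eye(C.n) + C.C)
        for _ in range(100_000):
            nv = m @ v
            nv /= nv.sum()
            if np.max(np.abs(nv - v)) < 1e-14:
                v = nv
                break
            v = nv
    v = np.clip(v, 0.0, None)
    return StationaryDistribution(v / v.sum())


def halting_distribution(C: TransitionMatrix, q: float) -> np.ndarray:
    """Matrix q (I + Omega(q)): column j is the distribution of the node
    where a stopped walk launched at j halts (the halt test precedes the
    first hop, so the start node keeps at least mass q)."""
    omega = walk_propagator(C, q).omega
    return q * (np.eye(C.n) + omega)
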