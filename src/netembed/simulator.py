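"""Exact stochastic implementation of the two-step assignment rule.

One step of the process: (1) pick an unassigned source node of network A
uniformly at random and assign it to location i of network B with
probability f_i; (2) for each currently unassigned neighbor of the source
in A, launch an attractiveness-weighted random walk on B from i with
per-step stopping probability q, and assign the neighbor to the halting
node. The halt test precedes the first hop, so a walk returns its start
node with probability at least q; at q=1 every neighbor lands on the
source's location, and the q -> 0 limit assigns neighbors directly from
the stationary distribution v0 of the walk (no infinite walks are
simulated). Neighbors assigned within a step do not cascade: their own
neighborhoods are not expanded until they would be drawn as sources,
which never happens since they are already assigned.

The run ends when every A-node is assigned, yielding the assignment map,
the realized populations Phi (counts per B-node) and the weighted
embedded adjacency Gamma, whose entry (i, j) counts A-edges between the
groups assigned to i and j (diagonal = within-location edges, counted
once). Optionally a per-step trace of the empirical degree moments over
the unassigned pool is recorded for mean-field validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .location_networks import AttractivenessVector, UndirectedGraph
from .spectral import build_transition_matrix, stationary_distribution

__all__ = [
    "EmbeddingRealization",
    "MomentTrace",
    "WalkTables",
    "choose_source",
    "choose_target",
    "stopped_walk",
    "run_embedding",
]


@dataclass(frozen=True)
class EmbeddingRealization:
    """Outcome of one full assignment run."""

    assignment: np.ndarray  # length N_A, B-node index per A-node
    phi: np.ndarray  # length N_B, integer counts
    gamma: np.ndarray  # N_B x N_B symmetric integer weights
    n_steps: int  # number of source selections (realized t*)
    q: float
    seed: object

    def save(self, outdir, prefix: str = "run") -> None:
        """CSV artifacts plus a JSON metadata sidecar."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"a_node": np.arange(self.assignment.size), "b_node": self.assignment}
        ).to_csv(outdir / f"{prefix}_assignment.csv", index=False)
        pd.DataFrame({"node": np.arange(self.phi.size), "phi": self.phi}).to_csv(
            outdir / f"{prefix}_phi.csv", index=False
        )
        ii, jj = np.nonzero(np.triu(self.gamma))
        pd.DataFrame({"i": ii, "j": jj, "weight": self.gamma[ii, jj]}).to_csv(
            outdir / f"{prefix}_gamma.csv", index=False
        )
        meta = {
            "q": self.q,
            "seed": None if self.seed is None else int(self.seed),
            "n_a": int(self.assignment.size),
            "n_b": int(self.phi.size),
            "n_steps": int(self.n_steps),
        }
        (outdir / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


@dataclass(frozen=True)
class MomentTrace:
    """Empirical moments over the unassigned pool, sampled before each
    source selection: eta, mean/second moment of unassigned-neighbor
    counts, mean assigned-neighbor count."""

    eta: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    kd: np.ndarray


class WalkTables:
    """Per-node neighbor lists and cumulative attractiveness weights for
    O(log deg) sampling of one hop of the weighted walk on B."""

    __slots__ = ("nbrs", "cum")

    def __init__(self, B: UndirectedGraph, f: AttractivenessVector) -> None:
        if len(f) != B.n_nodes:
            raise ValueError(f"f has length {len(f)} but B has {B.n_nodes} nodes")
        deg = B.degrees()
        if (deg == 0).any():
            raise ValueError(
                f"isolated node(s) in B: {np.flatnonzero(deg == 0).tolist()}"
            )
        self.nbrs = [B.neighbors(j).copy() for j in range(B.n_nodes)]
        self.cum = [np.cumsum(f.f[nb]) for nb in self.nbrs]

    def hop(self, node: int, rng: np.random.Generator) -> int:
        """One move j -> i with probability f_i B_ij / sum_l f_l B_lj."""
        cum = self.cum[node]
        u = rng.random() * cum[-1]
        return int(self.nbrs[node][np.searchsorted(cum, u, side="right")])


def choose_source(unassigned, rng: np.random.Generator) -> int:
    """Uniform draw over the currently unassigned A-nodes."""
    pool = list(unassigned) if not isinstance(unassigned, (list, np.ndarray)) else unassigned
    n = len(pool)
    if n == 0:
        raise IndexError("no unassigned nodes left: the process is complete")
    return int(pool[rng.integers(n)])


def choose_target(f: AttractivenessVector, rng: np.random.Generator) -> int:
    """Categorical draw of a B-node with probabilities f."""
    cum = np.cumsum(f.f)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))


def stopped_walk(
    start: int,
    B: UndirectedGraph,
    f: AttractivenessVector,
    q: float,
    rng: np.random.Generator,
    tables: WalkTables | None = None,
) -> int:
    """Weighted random walk from ``start`` with per-step stopping
    probability q; returns the halting node. The halt test is applied at
    the start node before any move. The q -> 0 limit is a separate code
    path (sampling from v0), so q must be positive here."""
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    if tables is None:
        tables = WalkTables(B, f)
    node = int(start)
    while rng.random() >= q:
        node = tables.hop(node, rng)
    return node


def run_embedding(
    A: UndirectedGraph,
    B: UndirectedGraph,
    f: AttractivenessVector,
    q: float,
    seed=None,
    trace: bool = False,
):
    """Run the assignment rule to exhaustion.

    Parameters
    ----------
    A, B : UndirectedGraph
        The embedded network and the location network. ``N_A > N_B`` is
        the regime the model is meant for (a warning is emitted
        otherwise); B must have no isolated nodes.
    f : AttractivenessVector
        Attractiveness of the B-nodes.
    q : float
        Stopping probability in [0, 1]; ``q = 0`` means the delocalized
        limit (neighbors drawn from the stationary distribution).
    seed : int, Generator or None
        Single RNG stream for the whole run.
    trace : bool
        Also record the per-step :class:`MomentTrace`.

    Returns
    -------
    EmbeddingRealization, or ``(EmbeddingRealization, MomentTrace)`` when
    ``trace`` is set.
    """
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if A.n_nodes <= B.n_nodes:
        import warnings

        warnings.warn(
            f"N_A={A.n_nodes} <= N_B={B.n_nodes}: the model targets N_A > N_B",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_a = A.n_nodes

    tables = WalkTables(B, f)
    f_cum = np.cumsum(f.f)
    if q == 0.0:
        v0 = stationary_distribution(build_transition_matrix(B, f), graph=B).v0
        v0_cum = np.cumsum(v0)

    # uniform sampling from a shrinking pool via swap-removal
    pool = np.arange(n_a, dtype=np.int64)
    pos = np.arange(n_a, dtype=np.int64)  # pos[node] = index in pool
    pool_size = n_a
    assignment = np.full(n_a, -1, dtype=np.int64)

    if trace:
        # incremental per-node unassigned/assigned neighbor counts
        u_nbrs = A.degrees().astype(np.int64)
        a_nbrs = np.zeros(n_a, dtype=np.int64)
        s1 = float(u_nbrs.sum())
        s2 = float((u_nbrs.astype(float) ** 2).sum())
        sd = 0.0
        tr_eta, tr_k1, tr_k2, tr_kd = [], [], [], []

    def remove_from_pool(node: int) -> None:
        nonlocal pool_size
        p = pos[node]
        last = pool[pool_size - 1]
        pool[p] = last
        pos[last] = p
        pool_size -= 1

    def mark_assigned(node: int) -> None:
        nonlocal s1, s2, sd
        # node leaves the unassigned pool: drop its terms from the sums,
        # then update its neighbors' split counts
        s1 -= u_nbrs[node]
        s2 -= float(u_nbrs[node]) ** 2
        sd -= a_nbrs[node]
        for w in A.neighbors(node):
            if assignment[w] < 0:
                uw = u_nbrs[w]
                s1 -= 1.0
                s2 += -2.0 * uw + 1.0
                sd += 1.0
            u_nbrs[w] -= 1
            a_nbrs[w] += 1

    n_steps = 0
    while pool_size > 0:
        if trace:
            eta = pool_size
            tr_eta.append(eta)
            tr_k1.append(s1 / eta)
            tr_k2.append(s2 / eta)
            tr_kd.append(sd / eta)
        src = int(pool[rng.integers(pool_size)])
        tgt = int(np.searchsorted(f_cum, rng.random() * f_cum[-1], side="right"))
        assignment[src] = tgt
        remove_from_pool(src)
        if trace:
            mark_assigned(src)
        n_steps += 1
        for nb in A.neighbors(src):
            if assignment[nb] >= 0:
                continue
            if q == 1.0:
                loc = tgt
            elif q == 0.0:
                loc = int(np.searchsorted(v0_cum, rng.random() * v0_cum[-1], side="right"))
            else:
                node = tgt
                while rng.random() >= q:
                    node = tables.hop(node, rng)
                loc = node
            assignment[nb] = loc
            remove_from_pool(nb)
            if trace:
                mark_assigned(nb)

    if trace:
        # terminal record: empty pool (moments of an empty set taken as 0)
        tr_eta.append(0)
        tr_k1.append(0.0)
        tr_k2.append(0.0)
        tr_kd.append(0.0)

    phi = np.bincount(assignment, minlength=B.n_nodes)
    gamma = np.zeros((B.n_nodes, B.n_nodes), dtype=np.int64)
    if A.n_edges:
        loc_u = assignment[A.edges[:, 0]]
        loc_v = assignment[A.edges[:, 1]]
        lo = np.minimum(loc_u, loc_v)
        hi = np.maximum(loc_u, loc_v)
        np.add.at(gamma, (lo, hi), 1)
        upper = np.triu(gamma, 1)
        gamma = gamma + upper.T  # symmetrize off-diagonal, diagonal stays once

    real = EmbeddingRealization(
        assignment=assignment,
        phi=phi,
        gamma=gamma,
        n_steps=n_steps,
        q=q,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
    if trace:
        mt = MomentTrace(
            eta=np.array(tr_eta, dtype=np.int64),
            k1=np.array(tr_k1),
            k2=np.array(tr_k2),
            kd=np.array(tr_kd),
        )
        return real, mt
    return real
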