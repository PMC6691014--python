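"""Mean-field description of the assignment process on network A.

The state of the process at (continuous) time t is summarized by four
moments of the unassigned population: eta(t), the number of unassigned
nodes; k1(t) and k2(t), the first and second moments of the number of
*unassigned* neighbors of an unassigned node; and kd(t), the mean number
of *assigned* neighbors of an unassigned node.

One step removes a uniformly chosen source (unassigned-degree k ~ P)
together with its k unassigned neighbors, each reached along an edge and
hence size-biased (k' ~ k' P(k') / k1). On a locally tree-like network
with no degree-degree correlations the expected one-step changes of the
moment sums close over (eta, k1, k2, kd) except for the third raw moment
k3 of P, for which we use the Poisson-type skewness closure
mu3 = k2 - k1^2 (third central moment equals the variance, exact for a
Poisson law; the unassigned-degree distribution of an ER graph starts
Poisson and stays approximately Poisson under the size-biased thinning).
Writing D = eta - 1 - k1 and k3 = 3 k1 k2 - 2 k1^3 + mu3:

    d k1 / dt = [k1^2 + k1 - 2 k2] / D
    d k2 / dt = [-k3 - 2 k2^2 / k1 + 3 k2 - k1 + k1 k2] / D
    d kd / dt = [k2 - k1] / D
    d eta / dt = -(1 + k1)

from the initial conditions eta(0) = N_A, k1(0) = <k>_A, k2(0) = <k^2>_A,
kd(0) = 0. The eta closure (one source plus its k1 expected unassigned
neighbors leave the pool per step) is the unique smooth closure consistent
with the completion condition N_A = int_0^{t*} [1 + k1(t)] dt, which
defines the completion time t*. The tree-like/uncorrelated assumptions
mean accuracy degrades on clustered or degree-correlated networks, and
the continuum description degrades once the pool is nearly empty
(eta = O(10)); see docs/methods.md for the derivation and its validation
against direct simulation.

Time integrals of the trajectory up to t* summarize everything the
downstream predictions need:

    alpha    = int k1 dt = N_A - t*   nodes embedded through the walk process
    beta     = int [k2 - k1 + k1 kd] dt     stubs placed via f at source steps
    gamma    = N_A <k>_A - 2 alpha - beta   stubs attached to walked nodes
    delta(q) = int [1 + q k1] dt = t* + q alpha

``gamma`` is fixed by exact stub conservation (every A-edge is either one
of the alpha synchronous pairs, consuming two stubs, or contributes its
two stubs to beta + gamma); the direct quadrature int kd dt is exposed as
``gamma_quad`` and agrees with it only to the accuracy of the moment
closure (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .location_networks import DegreeMoments

__all__ = [
    "TerminalRegime",
    "MomentTrajectory",
    "IntegralSummaries",
    "moment_derivatives",
    "integrate_moments",
    "summaries",
    "convergence_check",
]

logger = logging.getLogger(__name__)

#: integration stops when eta - 1 - k1 falls below this multiple of N_A
GUARD_FRACTION = 1e-6


class TerminalRegime(RuntimeError):
    """Raised when the moment ODE denominator eta - 1 - k1 is no longer
    positive: the integrator has entered the terminal regime and must
    stop and resolve t* by interpolation/extrapolation instead."""


@dataclass(frozen=True)
class MomentTrajectory:
    """RK4 solution of the moment system on a fixed grid, up to the guard
    point, plus the completion time t* resolved beyond it."""

    t: np.ndarray
    eta: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    kd: np.ndarray
    t_star: float
    n_nodes: int
    mean_k: float
    t_star_branch: str  # "interpolated" | "extrapolated"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "eta": self.eta, "k1": self.k1, "k2": self.k2, "kd": self.kd}
        )


@dataclass(frozen=True)
class IntegralSummaries:
    """Trajectory integrals up to t* feeding all analytic predictions.

    All four of alpha, beta, gamma and delta(q) come from one shared
    trajectory so that stub conservation ties the pieces together.
    """

    alpha: float
    beta: float
    gamma: float
    alpha_quad: float
    gamma_quad: float
    t_star: float
    n_nodes: int
    mean_k: float

    def delta_of_q(self, q: float) -> float:
        """delta(q) = int_0^{t*} [1 + q k1] dt, affine in q."""
        return self.t_star + q * self.alpha


def moment_derivatives(state) -> tuple[float, float, float, float]:
    """Right-hand side (d_eta, d_k1, d_k2, d_kd) at ``state = (eta, k1, k2, kd)``.

    Raises :class:`TerminalRegime` when eta - 1 - k1 <= 0. The k2/k1 term
    is taken as 0 when k1 = 0 (then k2 = 0 too for a degree distribution,
    the empty-network limit where only sources get assigned).
    """
    eta, k1, k2, kd = state
    d = eta - 1.0 - k1
    if d <= 0.0:
        raise TerminalRegime(f"denominator eta-1-k1 = {d} <= 0")
    d_k1 = (k1 * k1 + k1 - 2.0 * k2) / d
    if k1 > 0.0:
        mu3 = k2 - k1 * k1
        k3 = 3.0 * k1 * k2 - 2.0 * k1**3 + mu3
        d_k2 = (-k3 - 2.0 * k2 * k2 / k1 + 3.0 * k2 - k1 + k1 * k2) / d
    else:
        d_k2 = 0.0
    d_kd = (k2 - k1) / d
    return (-(1.0 + k1), d_k1, d_k2, d_kd)


def integrate_moments(
    moments: DegreeMoments,
    step: float = 0.1,
    tol_guard: float | None = None,
) -> MomentTrajectory:
    """Classical fixed-step RK4 from the exact initial conditions.

    Integration halts at the first step that would push the denominator
    eta - 1 - k1 at or below ``tol_guard`` (default ``1e-6 * N_A``); t*
    is then located from the completion condition
    ``int_0^{t*} [1 + k1] dt = N_A``, i.e. where eta reaches 0 — by
    linear interpolation if the integral crosses N_A on the grid, else
    by extrapolating with the last valid k1.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    n_a = moments.n_nodes
    if tol_guard is None:
        tol_guard = GUARD_FRACTION * n_a
    state = np.array([float(n_a), moments.mean_k, moments.mean_k2, 0.0])
    ts = [0.0]
    states = [state.copy()]
    t = 0.0
    # near the terminal singularity the guard crossing is resolved by
    # halving the step, so t* converges with the nominal step size
    h = step
    h_min = step / 256.0
    while True:
        try:
            nxt = _rk4_step(state, h)
        except TerminalRegime:
            nxt = None
        if nxt is None or nxt[0] - 1.0 - nxt[1] <= tol_guard or nxt[1] < 0.0 or nxt[0] <= 0.0:
            if h > h_min:
                h /= 2.0
                continue
            break
        # clamp tiny Jensen violations from roundoff; larger ones are bugs
        gap = nxt[2] - nxt[1] ** 2
        if gap < 0.0:
            if gap < -1e-9 and nxt[0] > 2.0 + nxt[1]:
                raise RuntimeError(f"moment integration lost k2 >= k1^2 (gap={gap:.3e})")
            nxt[2] = nxt[1] ** 2
        state = nxt
        t += h
        ts.append(t)
        states.append(state.copy())
    arr = np.array(states)
    t_grid = np.array(ts)
    eta, k1 = arr[:, 0], arr[:, 1]
    # cumulative int [1 + k1] dt = N_A - eta on the grid (exact under the closure)
    if eta[-1] <= 0.0:
        # crossed zero on the grid: interpolate
        idx = int(np.argmax(eta <= 0.0))
        frac = eta[idx - 1] / (eta[idx - 1] - eta[idx])
        t_star = t_grid[idx - 1] + frac * step
        branch = "interpolated"
    else:
        t_star = t_grid[-1] + eta[-1] / (1.0 + k1[-1])
        branch = "extrapolated"
    logger.debug("t* = %.6f resolved by %s (guard at eta=%.3g)", t_star, branch, eta[-1])
    return MomentTrajectory(
        t=t_grid,
        eta=eta,
        k1=k1,
        k2=arr[:, 2],
        kd=arr[:, 3],
        t_star=float(t_star),
        n_nodes=n_a,
        mean_k=moments.mean_k,
        t_star_branch=branch,
    )


def _rk4_step(state: np.ndarray, h: float) -> np.ndarray:
    f1 = np.array(moment_derivatives(state))
    f2 = np.array(moment_derivatives(state + 0.5 * h * f1))
    f3 = np.array(moment_derivatives(state + 0.5 * h * f2))
    f4 = np.array(moment_derivatives(state + h * f3))
    return state + (h / 6.0) * (f1 + 2.0 * f2 + 2.0 * f3 + f4)


def summaries(traj: MomentTrajectory) -> IntegralSummaries:
    """Composite-trapezoid quadrature of the stored grid, extended from
    the guard point to t* with the last valid integrand values (the tail
    where the unassigned pool is a handful of isolated nodes)."""
    if traj.t_star is None or not np.isfinite(traj.t_star):
        raise ValueError("trajectory has no completion time t_star")
    t, k1, k2, kd = traj.t, traj.k1, traj.k2, traj.kd
    tail = max(traj.t_star - t[-1], 0.0)
    # the completion condition int [1 + k1] dt = N_A makes alpha = N_A - t*
    # an identity; t* carries the RK4 accuracy, whereas direct trapezoid
    # quadrature of k1 is kept only as a diagnostic
    alpha = float(traj.n_nodes - traj.t_star)
    alpha_quad = float(trapezoid(k1, t) + k1[-1] * tail)
    beta_integrand = k2 - k1 + k1 * kd
    beta = float(trapezoid(beta_integrand, t) + beta_integrand[-1] * tail)
    gamma_quad = float(trapezoid(kd, t) + kd[-1] * tail)
    gamma = traj.n_nodes * traj.mean_k - 2.0 * alpha - beta
    return IntegralSummaries(
        alpha=alpha,
        alpha_quad=alpha_quad,
        beta=beta,
        gamma=gamma,
        gamma_quad=gamma_quad,
        t_star=traj.t_star,
        n_nodes=traj.n_nodes,
        mean_k=traj.mean_k,
    )


def convergence_check(moments: DegreeMoments, step: float = 0.1, rtol: float = 1e-4) -> dict:
    """Integrate at ``step`` and ``step/2`` and report the relative change
    of (alpha, beta, t*); raises if the change exceeds ``rtol``."""
    s1 = summaries(integrate_moments(moments, step=step))
    s2 = summaries(integrate_moments(moments, step=step / 2.0))
    rel = {
        name: abs(getattr(s1, name) - getattr(s2, name)) / max(abs(getattr(s2, name)), 1e-30)
        for name in ("alpha", "beta", "t_star")
    }
    worst = max(rel.values())
    if worst > rtol:
        raise RuntimeError(f"RK4 step {step} not converged: relative changes {rel}")
    return rel
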