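"""Closed-form expectations of the embedding outcome.

Given the integral summaries (alpha, beta, gamma, delta(q), t*) of one
mean-field trajectory and the spectral objects of network B, this module
assembles the analytic expected realized populations <Phi> and the
expected embedded adjacency <Gamma>.

Populations. For 0 < q < 1,

    <Phi_i> = f_i delta(q) + q alpha sum_j f_j Omega(q)_ij,

which sums to delta(q) + alpha (1-q) = t* + alpha = N_A exactly. At q=1
this collapses to <Phi_i> = N_A f_i, and in the q -> 0 limit

    <Phi_i> = f_i (N_A - alpha) + alpha v0_i.

Embedded adjacency. An A-edge is placed either synchronously (source and
neighbor in the same step, correlated through one walk) or asynchronously
(stub-paired at random). The synchronous part is the matrix psi; the
asynchronous part pairs the stub counts phi_i:

    <Gamma_ij> = psi_ij + (phi_i phi_j / sum_l phi_l) (1 - delta_ij / 2),

with, for q != 0 (omega_ij = f_j Omega(q)_ij),

    psi_ij = q alpha f_i delta_ij + q alpha (omega_ij + omega_ji) (1 - delta_ij / 2)
    phi_i  = (q beta + gamma) f_i + q beta sum_l f_l Omega(q)_il,

and for q = 0,

    psi_ij = alpha (f_i v0_j + f_j v0_i) (1 - delta_ij / 2)
    phi_i  = gamma f_i + beta v0_i.

Total masses are exact: sum_{i<=j} psi = alpha, sum_i phi = beta + gamma,
so sum_{i<=j} <Gamma> = alpha + (beta + gamma)/2 = N_A <k>_A / 2 = |E_A|.
At q=1 (Omega = 0) the assembly reduces to the shortcut

    <Gamma_ij> = f_i alpha delta_ij + f_i f_j (N_A <k>_A - 2 alpha) (1 - delta_ij / 2),

which depends only on the attractiveness of B and A's mean degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .location_networks import AttractivenessVector
from .meanfield import IntegralSummaries
from .spectral import StationaryDistribution, WalkPropagator

__all__ = [
    "Prediction",
    "predict_populations",
    "synchronous_matrix",
    "stub_vector",
    "predict_embedded",
    "predict",
]


@dataclass(frozen=True)
class Prediction:
    """Analytic <Phi> vector and <Gamma> matrix for one (A-moments, B, f, q)."""

    phi_mean: np.ndarray
    gamma_mean: np.ndarray
    q: float
    provenance: str  # "general-q" | "q=1" | "q=0"

    def save(self, outdir, prefix: str = "predicted") -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"node": np.arange(self.phi_mean.size), "phi": self.phi_mean}
        ).to_csv(outdir / f"{prefix}_phi.csv", index=False)
        ii, jj = np.triu_indices(self.gamma_mean.shape[0])
        pd.DataFrame({"i": ii, "j": jj, "weight": self.gamma_mean[ii, jj]}).to_csv(
            outdir / f"{prefix}_gamma.csv", index=False
        )


def _check_spectral(q: float, spectral) -> None:
    if q == 0.0:
        if not isinstance(spectral, StationaryDistribution):
            raise TypeError("q=0 predictions need the StationaryDistribution v0")
    else:
        if not isinstance(spectral, WalkPropagator):
            raise TypeError("q>0 predictions need the WalkPropagator Omega(q)")
        if abs(spectral.q - q) > 1e-12:
            raise ValueError(f"propagator was built for q={spectral.q}, requested q={q}")


def predict_populations(
    summaries: IntegralSummaries,
    spectral,
    f: AttractivenessVector,
    q: float,
    n_a: int | None = None,
) -> np.ndarray:
    """Expected realized populations <Phi> for the given q.

    ``spectral`` is the :class:`WalkPropagator` at q for q in (0, 1] or
    the :class:`StationaryDistribution` for q = 0.
    """
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q}")
    n_a = summaries.n_nodes if n_a is None else n_a
    fv = f.f
    if q == 1.0:
        return n_a * fv
    if q == 0.0:
        _check_spectral(q, spectral)
        return fv * (n_a - summaries.alpha) + summaries.alpha * spectral.v0
    _check_spectral(q, spectral)
    if len(f) != spectral.omega.shape[0]:
        raise ValueError("f and Omega have mismatched dimensions")
    return fv * summaries.delta_of_q(q) + q * summaries.alpha * (spectral.omega @ fv)


def synchronous_matrix(
    summaries: IntegralSummaries,
    spectral,
    f: AttractivenessVector,
    q: float,
) -> np.ndarray:
    """Expected adjacency psi of synchronously assigned edges; its total
    upper-triangle mass is alpha for every q."""
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q}")
    fv = f.f
    a = summaries.alpha
    if q == 0.0:
        _check_spectral(q, spectral)
        v0 = spectral.v0
        psi = a * (np.outer(fv, v0) + np.outer(v0, fv))
        np.fill_diagonal(psi, a * fv * v0)  # diagonal halved by (1 - delta/2)
        return psi
    _check_spectral(q, spectral)
    if len(f) != spectral.omega.shape[0]:
        raise ValueError("f and Omega have mismatched dimensions")
    omega_w = spectral.omega * fv[None, :]  # omega_ij = f_j Omega_ij
    psi = q * a * (omega_w + omega_w.T)
    np.fill_diagonal(psi, q * a * fv + q * a * np.diag(omega_w))
    return psi


def stub_vector(
    summaries: IntegralSummaries,
    spectral,
    f: AttractivenessVector,
    q: float,
) -> np.ndarray:
    """Expected stub counts phi per B-node; sums to beta + gamma for
    every q."""
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q}")
    fv = f.f
    b, g = summaries.beta, summaries.gamma
    if q == 0.0:
        _check_spectral(q, spectral)
        return g * fv + b * spectral.v0
    _check_spectral(q, spectral)
    if len(f) != spectral.omega.shape[0]:
        raise ValueError("f and Omega have mismatched dimensions")
    return (q * b + g) * fv + q * b * (spectral.omega @ fv)


def predict_embedded(
    summaries: IntegralSummaries,
    spectral,
    f: AttractivenessVector,
    q: float,
    n_a: int | None = None,
    mean_k: float | None = None,
) -> np.ndarray:
    """Expected embedded adjacency <Gamma> = psi + random stub pairing.

    At q=1 the closed-form shortcut is used and cross-checked against the
    general assembly (they agree to rounding because gamma satisfies stub
    conservation exactly).
    """
    n_a = summaries.n_nodes if n_a is None else n_a
    mean_k = summaries.mean_k if mean_k is None else mean_k
    psi = synchronous_matrix(summaries, spectral, f, q)
    phi = stub_vector(summaries, spectral, f, q)
    total = phi.sum()
    if total <= 0.0:
        if psi.sum() > 1e-12:
            raise ValueError("inconsistent summaries: zero stubs but nonzero psi mass")
        pairing = np.zeros_like(psi)
    else:
        pairing = np.outer(phi, phi) / total
        np.fill_diagonal(pairing, phi**2 / (2.0 * total))
    gamma_mean = psi + pairing
    if q == 1.0:
        fv = f.f
        shortcut = np.outer(fv, fv) * (n_a * mean_k - 2.0 * summaries.alpha)
        np.fill_diagonal(
            shortcut, fv * summaries.alpha + fv**2 * (n_a * mean_k - 2.0 * summaries.alpha) / 2.0
        )
        if not np.allclose(shortcut, gamma_mean, rtol=0.0, atol=1e-10):
            raise AssertionError("q=1 shortcut disagrees with the general assembly")
        return shortcut
    return gamma_mean


def predict(
    summaries: IntegralSummaries,
    spectral,
    f: AttractivenessVector,
    q: float,
    n_a: int | None = None,
) -> Prediction:
    """Bundle <Phi> and <Gamma> into a :class:`Prediction`."""
    phi_mean = predict_populations(summaries, spectral, f, q, n_a=n_a)
    gamma_mean = predict_embedded(summaries, spectral, f, q, n_a=n_a)
    provenance = {0.0: "q=0", 1.0: "q=1"}.get(q, "general-q")
    return Prediction(phi_mean=phi_mean, gamma_mean=gamma_mean, q=q, provenance=provenance)
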