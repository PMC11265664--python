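"""Maximum-a-posteriori prediction of varietal genetic effects.

With theta fixed at its estimate, the posterior mode
``u_hat = argmax_u p(u | y; theta_hat)`` is found by a second SAEM run in
which ``phi`` is the latent variable and ``u`` the quantity maximized:
Metropolis transitions on ``phi`` given the current ``u``, stochastic
approximation of the phi statistics, then a closed-form update

    u = (sum_i Z_i' P^-1 Z_i + K^-1 (x) G^-1)^-1
        sum_i Z_i' P^-1 (phibar_i - X_i beta)

where ``phibar`` is the SA-averaged phi.  The update includes the Gaussian
prior term ``log p(u; K (x) G)``: without it the maximizer would be the
profile estimate, not the posterior mode.  Because theta is fixed, the
system matrix is constant and factorized once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg

from .model_core import (
    Dataset,
    DesignMatrices,
    DesignSpec,
    Kinship,
    Theta,
    build_designs,
    chol_lower,
    spd_inverse,
    symmetrize,
)
from .saem_fit import SAEMSettings, mh_transition_phi, initialize_theta

__all__ = ["MAPResult", "map_settings", "map_u"]


def map_settings(seed: int = 0, **overrides) -> SAEMSettings:
    """Default schedule for effect prediction: 1000 iterations, 800 burn-in."""
    params = {"n_iter": 1000, "n_burn": 800, "seed": seed}
    params.update(overrides)
    return SAEMSettings(**params)


@dataclass
class MAPResult:
    u_hat: np.ndarray  # (q * N_v,) variety-major
    trajectory: np.ndarray  # per-iteration ||u||
    settings: SAEMSettings

    def effects_matrix(self, q: int) -> np.ndarray:
        return self.u_hat.reshape(-1, q)


def map_u(
    dataset: Dataset,
    spec: DesignSpec,
    kinship: Kinship,
    theta_hat: Theta,
    settings: Optional[SAEMSettings] = None,
    designs: Optional[DesignMatrices] = None,
) -> MAPResult:
    """SAEM maximum-a-posteriori estimate of the varietal genetic effects."""
    if settings is None:
        settings = map_settings()
    if designs is None:
        designs = build_designs(dataset, spec)
    kinship.aligned_to(dataset)
    curve = spec.get_curve()
    rng = np.random.default_rng(settings.seed)
    n_v, q, m = kinship.n, designs.q, designs.m

    p_inv = spd_inverse(theta_hat.P, "P")
    k_inv = spd_inverse(kinship.K, "K")
    g_inv = spd_inverse(theta_hat.G, "G")

    blocks = np.einsum("imq,mn,inr->iqr", designs.Zb, p_inv, designs.Zb, optimize=True)
    data_prec = np.zeros((n_v, q, q))
    np.add.at(data_prec, designs.v_idx, blocks)
    precision = np.kron(k_inv, g_inv)
    for v in range(n_v):
        sl = slice(v * q, (v + 1) * q)
        precision[sl, sl] += data_prec[v]
    low = chol_lower(symmetrize(precision), "u update system")

    _, phi = initialize_theta(designs, curve)
    u = np.zeros(q * n_v)
    scales = np.full(m, 1.0)
    phibar = phi.copy()
    traj = np.empty(settings.n_iter)

    offset = designs.X @ theta_hat.beta  # (N_p, m)
    for k in range(1, settings.n_iter + 1):
        gamma = 1.0 if k <= settings.n_burn else float(k - settings.n_burn) ** (
            -settings.sa_exponent
        )
        phi, acc = mh_transition_phi(
            designs, curve, theta_hat, u, phi, scales, settings.mh_inner, rng
        )
        if k <= settings.n_burn:
            rate = min(0.5, 2.0 / np.sqrt(k))
            scales = np.clip(
                scales * np.exp(rate * (acc - settings.adapt_target)), 1e-8, 1e8
            )
        phibar = phibar + gamma * (phi - phibar)
        rhs_terms = np.einsum(
            "imq,mn,in->iq", designs.Zb, p_inv, phibar - offset, optimize=True
        )
        rhs = np.zeros((n_v, q))
        np.add.at(rhs, designs.v_idx, rhs_terms)
        u = linalg.cho_solve((low, True), rhs.ravel())
        traj[k - 1] = float(np.linalg.norm(u))

    return MAPResult(u_hat=u, trajectory=traj, settings=settings)
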