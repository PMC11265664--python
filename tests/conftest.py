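"""Shared fixtures and independent oracles.

The oracles here deliberately use brute-force dense linear algebra
(materialized Kronecker covariances, generic multivariate-normal densities,
joint-Gaussian conditioning, numerical likelihood maximization) so they
stay independent of the factorized code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize, stats

from growsaem import (
    Dataset,
    Kinship,
    PlantRecord,
    Theta,
    build_designs,
    design_from_terms,
)


def random_spd(dim: int, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """A well-conditioned random symmetric positive-definite matrix."""
    a = rng.standard_normal((dim, dim))
    return scale * (a @ a.T / dim + np.eye(dim))


def random_kinship(n: int, rng: np.random.Generator) -> np.ndarray:
    k = random_spd(n, rng, 0.5)
    d = np.sqrt(np.diag(k))
    k = k / np.outer(d, d)  # correlation-like, unit diagonal
    return 0.5 * (k + k.T)


def make_instance(
    n_varieties: int,
    plants_per_variety: int,
    curve: str = "logistic",
    fixed_terms=("1",),
    genetic_terms=("1",),
    times=(5.0, 15.0, 30.0),
    covariate_values=None,
    seed: int = 0,
    theta: Theta | None = None,
):
    """Small synthetic instance with everything materialized for oracles."""
    rng = np.random.default_rng(seed)
    spec = design_from_terms(curve, list(fixed_terms), list(genetic_terms))
    m = spec.get_curve().m
    q = spec.q
    varieties = [f"v{j}" for j in range(n_varieties)]
    kin = Kinship(random_kinship(n_varieties, rng), varieties)
    if theta is None:
        if curve == "logistic":
            beta = np.concatenate([[50.0, 13.0], 0.1 * rng.standard_normal(spec.p - 2)])
        else:
            beta = 5.0 + rng.standard_normal(spec.p)
        theta = Theta(
            beta=beta,
            sigma2=1.0,
            P=random_spd(m, rng, 0.5),
            G=random_spd(q, rng, 0.8),
        )
    plants = []
    n_p = n_varieties * plants_per_variety
    for i in range(n_p):
        v = i % n_varieties
        covs = {}
        if covariate_values is not None:
            covs = {"x": float(covariate_values[i % len(covariate_values)])}
        plants.append(
            PlantRecord(
                plant_id=f"p{i}",
                variety=varieties[v],
                covariates=covs,
                times=np.array(times, dtype=float),
                values=np.zeros(len(times)),
            )
        )
    dataset = Dataset(plants, {v: j for j, v in enumerate(varieties)})
    designs = build_designs(dataset, spec)
    # simulate observations from the model itself
    l_k = np.linalg.cholesky(kin.K)
    l_g = np.linalg.cholesky(theta.G)
    u_mat = l_k @ rng.standard_normal((n_varieties, q)) @ l_g.T
    u = u_mat.ravel()
    l_p = np.linalg.cholesky(theta.P)
    phi = designs.phi_mean(theta.beta, u) + rng.standard_normal((n_p, m)) @ l_p.T
    curve_obj = spec.get_curve()
    values = curve_obj.evaluate(phi, designs.times)
    values = values + np.sqrt(theta.sigma2) * rng.standard_normal(values.shape)
    for i, rec in enumerate(dataset.plants):
        rec.values = values[i, : rec.n_obs].copy()
    designs = build_designs(dataset, spec)
    return dict(
        dataset=dataset, spec=spec, kinship=kin, theta=theta, designs=designs,
        phi=phi, u=u, rng=rng,
    )


# ---------------------------------------------------------------------------
# dense oracles


def dense_z_full(designs, n_varieties: int) -> np.ndarray:
    """Materialize the full (N_p m) x (q N_v) incidence matrix (oracle only)."""
    n_p, m, q = designs.n_plants, designs.m, designs.q
    z = np.zeros((n_p * m, q * n_varieties))
    for i in range(n_p):
        v = designs.v_idx[i]
        z[i * m : (i + 1) * m, v * q : (v + 1) * q] = designs.Zb[i]
    return z


def oracle_complete_loglik(designs, curve, theta, kinship, phi, u) -> float:
    """Three explicit multivariate-normal densities on dense covariances."""
    total = 0.0
    for i in range(designs.n_plants):
        msk = designs.mask[i]
        mean = curve.evaluate(phi[i], designs.times[i, msk])
        total += stats.multivariate_normal.logpdf(
            designs.values[i, msk], mean=mean,
            cov=theta.sigma2 * np.eye(int(msk.sum())),
        )
    mean_phi = designs.phi_mean(theta.beta, u)
    for i in range(designs.n_plants):
        total += stats.multivariate_normal.logpdf(
            phi[i], mean=mean_phi[i], cov=theta.P
        )
    cov_u = np.kron(kinship.K, theta.G)
    total += stats.multivariate_normal.logpdf(u, mean=np.zeros(u.size), cov=cov_u)
    return float(total)


def oracle_u_conditional(designs, theta, kinship, phi):
    """Brute-force conditioning of the jointly Gaussian (phi, u) on phi."""
    n_v = kinship.n
    z = dense_z_full(designs, n_v)
    cov_u = np.kron(kinship.K, theta.G)
    cov_pp = z @ cov_u @ z.T
    for i in range(designs.n_plants):
        sl = slice(i * designs.m, (i + 1) * designs.m)
        cov_pp[sl, sl] += theta.P
    cov_up = cov_u @ z.T
    mean_phi = (designs.X @ theta.beta).ravel()
    solve = np.linalg.solve(cov_pp, (phi.ravel() - mean_phi))
    mean = cov_up @ solve
    cov = cov_u - cov_up @ np.linalg.solve(cov_pp, cov_up.T)
    return mean, 0.5 * (cov + cov.T)


def oracle_lmm_mle(dataset, kinship, sigma2_0=1.0, p_0=1.0, g_0=1.0):
    """Exact marginal ML for the constant-curve submodel y = beta + u_v + p_i + e.

    The marginal likelihood is Gaussian with per-variety block covariance
    G K_vv J + P I(plant) + sigma2 I(obs); maximized numerically over
    (beta, log sigma2, log P, log G).  Serves as the closed-form
    linear-mixed-model reference for the SAEM fit.
    """
    groups = {}
    for rec in dataset.plants:
        groups.setdefault(rec.variety, []).append(rec)

    def negloglik(params):
        beta, ls2, lp, lg = params
        s2, p_var, g_var = np.exp(ls2), np.exp(lp), np.exp(lg)
        total = 0.0
        for variety, recs in groups.items():
            v = dataset.variety_index[variety]
            k_vv = kinship.K[v, v]
            sizes = [r.n_obs for r in recs]
            n = sum(sizes)
            cov = np.full((n, n), g_var * k_vv)
            at = 0
            for sz in sizes:
                cov[at : at + sz, at : at + sz] += p_var
                at += sz
            cov += s2 * np.eye(n)
            y = np.concatenate([r.values for r in recs])
            total += stats.multivariate_normal.logpdf(y, mean=np.full(n, beta), cov=cov)
        return -total

    y_all = np.concatenate([r.values for r in dataset.plants])
    start = np.array(
        [y_all.mean(), np.log(sigma2_0), np.log(p_0), np.log(g_0)]
    )
    res = optimize.minimize(negloglik, start, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    beta, ls2, lp, lg = res.x
    return {"beta": beta, "sigma2": np.exp(ls2), "P": np.exp(lp), "G": np.exp(lg)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
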