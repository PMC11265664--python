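"""SAEM maximum-likelihood estimation of the model parameters.

The complete-data likelihood is, given ``(phi, u)``, an exponential family
in ``theta = (beta, sigma2, P, G)``; the stochastic approximation therefore
runs on the complete-data sufficient statistics rather than on the Q
function itself:

* ``rss``      -- sum of squared observation residuals (drives sigma2),
* per covariate pattern ``c``: sums and cross-products of
  ``r_i = phi_i - Z_i u`` over plants in the pattern (drive beta and P),
* ``S(u) = sum_{v,w} [K^-1]_{vw} u_v u_w'`` (drives G).

Each iteration: (1) simulation -- a few random-walk Metropolis transitions
per plant on ``phi_i`` targeting ``p(phi_i | u, y_i; theta)`` (plants are
conditionally independent given ``u``), then an exact Gaussian draw of
``u | phi``; (2) stochastic-approximation update of the statistics with
step size ``gamma_k`` (1 during burn-in, then ``(k - n_burn)^(-a)``);
(3) closed-form M-step.  Proposal scales are adapted toward a target
acceptance rate during burn-in only and frozen afterwards so the SAEM
convergence conditions hold in the refining phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import linalg, optimize

from .growth_models import GrowthCurve
from .model_core import (
    Dataset,
    DesignMatrices,
    DesignSpec,
    Kinship,
    LatentState,
    NumericalError,
    Theta,
    build_designs,
    chol_lower,
    genetic_scatter,
    residual_ss,
    spd_inverse,
    spd_logdet,
    symmetrize,
    u_conditional,
)

__all__ = [
    "SAEMSettings",
    "SAStats",
    "FitResult",
    "step_size",
    "mh_transition_phi",
    "sample_u",
    "sa_update",
    "m_step",
    "q_objective",
    "initialize_theta",
    "fit",
]

SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class SAEMSettings:
    """Iteration schedule and Metropolis kernel tuning.

    Defaults follow the simulation-study schedule (1500 iterations with a
    1300-iteration burn-in); the real-data-scale schedule (400/300) is a
    matter of overriding ``n_iter``/``n_burn``.  ``sa_exponent`` must lie in
    (1/2, 1] so the step sizes satisfy sum gamma_k = inf, sum gamma_k^2 < inf.
    """

    n_iter: int = 1500
    n_burn: int = 1300
    sa_exponent: float = 2.0 / 3.0
    mh_inner: int = 5
    proposal_scale: Optional[np.ndarray] = None  # relative, in the P-Cholesky basis
    adapt_target: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.n_burn < self.n_iter:
            raise ValueError("need 0 <= n_burn < n_iter")
        if not 0.5 < self.sa_exponent <= 1.0:
            raise ValueError("sa_exponent must lie in (1/2, 1]")
        if self.mh_inner < 1:
            raise ValueError("mh_inner must be >= 1")


def step_size(k: int, settings: SAEMSettings) -> float:
    """gamma_k = 1 during burn-in, (k - n_burn)^(-sa_exponent) afterwards.

    The first post-burn-in step is 1, so the schedule is continuous.
    """
    if k < 1:
        raise ValueError("iterations are 1-based")
    if k <= settings.n_burn:
        return 1.0
    return float(k - settings.n_burn) ** (-settings.sa_exponent)


@dataclass
class SAStats:
    """SA accumulators of the complete-data sufficient statistics."""

    rss: float
    s1: np.ndarray  # (C, m) per-pattern residual sums
    s2: np.ndarray  # (C, m, m) per-pattern residual cross-products
    scatter: np.ndarray  # (q, q) genetic scatter S(u)

    def blend(self, new: "SAStats", gamma: float) -> "SAStats":
        return SAStats(
            rss=self.rss + gamma * (new.rss - self.rss),
            s1=self.s1 + gamma * (new.s1 - self.s1),
            s2=self.s2 + gamma * (new.s2 - self.s2),
            scatter=self.scatter + gamma * (new.scatter - self.scatter),
        )


def sa_update(stats: SAStats, new: SAStats, gamma: float) -> SAStats:
    """s <- s + gamma (s_new - s) fieldwise; gamma = 1 replaces outright."""
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    return stats.blend(new, gamma)


def conditional_statistics(
    designs: DesignMatrices,
    curve: GrowthCurve,
    phi: np.ndarray,
    u_mean: np.ndarray,
    u_cov: np.ndarray,
    k_inv: np.ndarray,
) -> SAStats:
    """Exact E[sufficient statistics | y, phi]: u integrated analytically.

    ``p(u | phi)`` is Gaussian and every u-statistic is quadratic in u, so
    the conditional expectations are available in closed form:

        E[r_i r_i' | phi] = rbar_i rbar_i' + Z_b Cov(u_v) Z_b',
        E[S(u)  | phi]    = M' K^-1 M + sum_{v,w} [K^-1]_{vw} Cov(u_v, u_w)

    with ``rbar_i = phi_i - Z_b E[u_v]`` and ``M`` the matrix of conditional
    means.  Using these instead of single-draw statistics removes the draw
    noise of ``u`` from the stochastic approximation; in particular the
    genetic covariance update can no longer be absorbed at zero by a few
    small draws, since the covariance term keeps E[S(u)] of order G while
    the mean term pulls it toward the data-supported value.
    """
    n_v, q = u_cov.shape[0] // designs.q, designs.q
    rss = float(residual_ss(designs, curve, phi).sum())
    mu_mat = u_mean.reshape(n_v, q)
    resid = phi - np.einsum(
        "imq,iq->im", designs.Zb, mu_mat[designs.v_idx], optimize=True
    )
    n_pat = len(designs.pattern_X)
    s1 = np.zeros((n_pat, designs.m))
    np.add.at(s1, designs.pattern_of, resid)

    cov_blocks = u_cov.reshape(n_v, q, n_v, q)
    diag_blocks = cov_blocks[np.arange(n_v), :, np.arange(n_v), :]  # (N_v, q, q)
    correction = np.einsum(
        "imq,iqr,inr->imn", designs.Zb, diag_blocks[designs.v_idx], designs.Zb,
        optimize=True,
    )
    cross = np.einsum("im,in->imn", resid, resid) + correction
    s2 = np.zeros((n_pat, designs.m, designs.m))
    np.add.at(s2, designs.pattern_of, cross)

    scatter = genetic_scatter(mu_mat, k_inv) + np.einsum(
        "vw,vawb->ab", k_inv, cov_blocks, optimize=True
    )
    return SAStats(rss=rss, s1=s1, s2=s2, scatter=symmetrize(scatter))


def draw_statistics(
    designs: DesignMatrices,
    curve: GrowthCurve,
    phi: np.ndarray,
    u: np.ndarray,
    k_inv: np.ndarray,
) -> SAStats:
    """Sufficient statistics of one latent draw ``(phi, u)``."""
    rss = float(residual_ss(designs, curve, phi).sum())
    u_mat = u.reshape(-1, designs.q)
    resid = phi - np.einsum(
        "imq,iq->im", designs.Zb, u_mat[designs.v_idx], optimize=True
    )
    n_pat = len(designs.pattern_X)
    s1 = np.zeros((n_pat, designs.m))
    np.add.at(s1, designs.pattern_of, resid)
    cross = np.einsum("im,in->imn", resid, resid)
    s2 = np.zeros((n_pat, designs.m, designs.m))
    np.add.at(s2, designs.pattern_of, cross)
    scatter = genetic_scatter(u_mat, k_inv)
    return SAStats(rss=rss, s1=s1, s2=s2, scatter=scatter)


# ---------------------------------------------------------------------------
# simulation step


def _phi_log_target(
    designs: DesignMatrices,
    curve: GrowthCurve,
    phi: np.ndarray,
    mean_phi: np.ndarray,
    p_inv: np.ndarray,
    sigma2: float,
) -> np.ndarray:
    """Per-plant log p(y_i | phi_i) + log p(phi_i | u), up to constants."""
    rss = residual_ss(designs, curve, phi)
    dev = phi - mean_phi
    quad = np.einsum("im,mn,in->i", dev, p_inv, dev, optimize=True)
    return -0.5 * (rss / sigma2 + quad)


def mh_transition_phi(
    designs: DesignMatrices,
    curve: GrowthCurve,
    theta: Theta,
    u: np.ndarray,
    phi: np.ndarray,
    scales: np.ndarray,
    n_inner: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Componentwise Gaussian random-walk Metropolis on each plant's phi_i.

    The walk runs in the Cholesky basis of the current ``P``: coordinate
    ``j`` moves along the ``j``-th Cholesky column, with a dimensionless
    relative scale.  Shaping the proposal by the prior covariance keeps the
    kernel effective when ``P`` develops strong correlations (an
    axis-aligned walk would be rejected almost surely on a near-singular
    ridge, freezing the chain and the SA statistics with it).

    Plants are conditionally independent given ``u``, so all chains advance
    in lock-step vectorized over plants.  Returns the new ``phi`` and the
    per-coordinate acceptance rates.
    """
    n_p, m = phi.shape
    mean_phi = designs.phi_mean(theta.beta, u)
    p_inv = spd_inverse(theta.P, "P")
    l_p = chol_lower(theta.P, "P")
    current = phi.copy()
    log_target = _phi_log_target(designs, curve, current, mean_phi, p_inv, theta.sigma2)
    if not np.all(np.isfinite(log_target)):
        bad = int(np.flatnonzero(~np.isfinite(log_target))[0])
        raise NumericalError(f"non-finite Metropolis target at plant index {bad}")
    accepted = np.zeros(m)
    for _ in range(n_inner):
        for j in range(m):
            step = scales[j] * rng.standard_normal(n_p)
            proposal = current + step[:, None] * l_p[:, j]
            prop_target = _phi_log_target(
                designs, curve, proposal, mean_phi, p_inv, theta.sigma2
            )
            log_ratio = prop_target - log_target
            accept = np.log(rng.random(n_p)) < log_ratio
            current[accept] = proposal[accept]
            log_target = np.where(accept, prop_target, log_target)
            accepted[j] += accept.mean()
    return current, accepted / n_inner


def sample_u(
    theta: Theta,
    kinship: Kinship,
    designs: DesignMatrices,
    phi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact draw from the Gaussian p(u | phi; theta) via its precision Cholesky."""
    mean, low = u_conditional(theta, kinship, designs, phi, return_chol=True)
    z = rng.standard_normal(mean.size)
    return mean + linalg.solve_triangular(low.T, z, lower=False)


# ---------------------------------------------------------------------------
# M-step


def m_step(
    stats: SAStats,
    designs: DesignMatrices,
    n_varieties: int,
    prev_theta: Optional[Theta] = None,
    tol: float = 1e-8,
    max_inner: int = 50,
) -> Theta:
    """Closed-form maximization of the SA-averaged complete-data likelihood.

    sigma2 and G have direct closed forms; beta and P solve a coupled GLS
    system iterated to a relative-change tolerance (the coupling is through
    P^-1 in the GLS weights).
    """
    total_n = designs.total_obs
    n_p = designs.n_plants
    m = designs.m

    sigma2 = stats.rss / total_n
    if sigma2 < SIGMA2_FLOOR:
        warnings.warn(
            "residual variance hit the lower floor; data may be noiseless",
            RuntimeWarning,
            stacklevel=2,
        )
        sigma2 = SIGMA2_FLOOR

    g_mat = symmetrize(stats.scatter / n_varieties)

    counts = designs.pattern_counts.astype(float)
    x_c = np.stack(designs.pattern_X)  # (C, m, p)
    p_mat = prev_theta.P.copy() if prev_theta is not None else np.eye(m)
    beta = None
    for _ in range(max_inner):
        p_inv = spd_inverse(p_mat, "P")
        lhs = np.einsum("c,cmp,mn,cnr->pr", counts, x_c, p_inv, x_c, optimize=True)
        rhs = np.einsum("cmp,mn,cn->p", x_c, p_inv, stats.s1, optimize=True)
        new_beta = np.linalg.solve(lhs, rhs)
        mu_c = x_c @ new_beta  # (C, m)
        center = (
            stats.s2
            - np.einsum("cm,cn->cmn", mu_c, stats.s1)
            - np.einsum("cm,cn->cmn", stats.s1, mu_c)
            + counts[:, None, None] * np.einsum("cm,cn->cmn", mu_c, mu_c)
        )
        new_p = symmetrize(center.sum(axis=0) / n_p)
        if beta is not None:
            denom = max(np.abs(beta).max(), np.abs(p_mat).max(), 1e-12)
            change = max(
                np.abs(new_beta - beta).max(), np.abs(new_p - p_mat).max()
            )
            if change < tol * denom:
                beta, p_mat = new_beta, new_p
                break
        beta, p_mat = new_beta, new_p
    else:
        warnings.warn(
            "beta/P inner GLS iteration did not converge; using last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    # floor eigenvalues at a relative 1e-8: keeps downstream Cholesky solves
    # well-posed when a variance matrix degenerates on a small sample
    p_mat = _floor_spd(p_mat)
    g_mat = _floor_spd(g_mat)
    return Theta(beta=beta, sigma2=sigma2, P=p_mat, G=g_mat)


def _floor_spd(mat: np.ndarray, rel: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(symmetrize(mat))
    floor = rel * max(float(vals.max()), 1e-12)
    if vals.min() >= floor:
        return symmetrize(mat)
    vals = np.clip(vals, floor, None)
    return symmetrize((vecs * vals) @ vecs.T)


def q_objective(
    stats: SAStats,
    theta: Theta,
    designs: DesignMatrices,
    kinship: Kinship,
) -> float:
    """SA-averaged complete-data log-likelihood Q(theta) at the given stats.

    The M-step maximizes this function; it is exposed so the closed forms
    can be checked against a general-purpose numerical optimizer.
    """
    total_n = designs.total_obs
    n_p, m = designs.n_plants, designs.m
    n_v, q = kinship.n, designs.q
    log2pi = np.log(2.0 * np.pi)

    term_y = -0.5 * (
        total_n * (log2pi + np.log(theta.sigma2)) + stats.rss / theta.sigma2
    )

    p_inv = spd_inverse(theta.P, "P")
    counts = designs.pattern_counts.astype(float)
    x_c = np.stack(designs.pattern_X)
    mu_c = x_c @ theta.beta
    center = (
        stats.s2
        - np.einsum("cm,cn->cmn", mu_c, stats.s1)
        - np.einsum("cm,cn->cmn", stats.s1, mu_c)
        + counts[:, None, None] * np.einsum("cm,cn->cmn", mu_c, mu_c)
    )
    quad = float(np.einsum("mn,cnm->", p_inv, center))
    term_phi = -0.5 * (n_p * (m * log2pi + spd_logdet(theta.P, "P")) + quad)

    g_inv = spd_inverse(theta.G, "G")
    term_u = -0.5 * (
        q * n_v * log2pi
        + q * spd_logdet(kinship.K, "K")
        + n_v * spd_logdet(theta.G, "G")
        + float(np.trace(g_inv @ stats.scatter))
    )
    return term_y + term_phi + term_u


# ---------------------------------------------------------------------------
# initialization


def _heuristic_phi(curve: GrowthCurve, times: np.ndarray, values: np.ndarray):
    """Curve-specific moment heuristics for one plant's starting phi."""
    vmax = float(values.max())
    if curve.name == "logistic":
        a = vmax if vmax > 0 else 1.0
        half = 0.5 * a
        above = values >= half
        x = float(times[above][0]) if above.any() else float(np.median(times))
        return np.array([a, x])
    if curve.name == "asymptotic_regression":
        a = vmax if vmax > 0 else 1.0
        # time to ~63% of the asymptote gives the rate constant
        above = values >= (1.0 - np.exp(-1.0)) * a
        t63 = float(times[above][0]) if above.any() else float(times[-1])
        t63 = max(t63, 1e-6)
        return np.array([a, np.log(1.0 / t63)])
    if curve.name == "constant":
        return np.array([float(values.mean())])
    return np.ones(curve.m)


def _per_plant_phi(designs: DesignMatrices, curve: GrowthCurve) -> np.ndarray:
    """Independent per-plant nonlinear least squares, heuristic fallback."""
    n_p, m = designs.n_plants, designs.m
    phi0 = np.empty((n_p, m))
    for i in range(n_p):
        t_i = designs.times[i, designs.mask[i]]
        y_i = designs.values[i, designs.mask[i]]
        start = _heuristic_phi(curve, t_i, y_i)
        phi0[i] = start
        if t_i.size <= m:
            continue  # underdetermined; keep the heuristic

        def resid(phi):
            return curve.evaluate(phi, t_i) - y_i

        try:
            sol = optimize.least_squares(resid, start, max_nfev=60)
            if np.all(np.isfinite(sol.x)):
                phi0[i] = sol.x
        except Exception:
            pass
    return phi0


def initialize_theta(
    designs: DesignMatrices, curve: GrowthCurve
) -> Tuple[Theta, np.ndarray]:
    """Starting (theta, phi) from independent per-plant curve fits.

    beta is the least-squares projection of the initial phi on the fixed
    design; P the covariance of the projection residuals; G a q-by-q
    identity at the scale of P with P's leading block copied in (the
    genetic effects enter phi through Z_block, which in the shipped designs
    shares P's trait layout); sigma2 the pooled residual variance of the
    per-plant fits.
    """
    phi0 = _per_plant_phi(designs, curve)
    m, p, q = designs.m, designs.p, designs.q

    lhs = np.einsum("imp,imr->pr", designs.X, designs.X, optimize=True)
    rhs = np.einsum("imp,im->p", designs.X, phi0, optimize=True)
    beta = np.linalg.solve(lhs + 1e-10 * np.eye(p), rhs)
    resid = phi0 - designs.X @ beta
    p_mat = symmetrize(resid.T @ resid / max(designs.n_plants - 1, 1))
    p_mat += 1e-6 * max(np.trace(p_mat) / m, 1.0) * np.eye(m)

    g_mat = np.eye(q) * max(np.trace(p_mat) / m, 1e-6)
    k = min(q, m)
    g_mat[:k, :k] = p_mat[:k, :k]
    g_mat = symmetrize(g_mat) + 1e-6 * np.eye(q)

    fitted = curve.evaluate(phi0, designs.times)
    rss = float((np.where(designs.mask, designs.values - fitted, 0.0) ** 2).sum())
    sigma2 = max(rss / designs.total_obs, 1e-8)
    return Theta(beta=beta, sigma2=sigma2, P=p_mat, G=g_mat), phi0


# ---------------------------------------------------------------------------
# main loop


@dataclass
class FitResult:
    """Estimate, per-iteration trajectory and diagnostics of one SAEM run."""

    theta: Theta
    trajectory: Dict[str, np.ndarray]
    acceptance: np.ndarray  # (n_iter, m)
    latent: LatentState
    settings: SAEMSettings
    theta_init: Theta

    def trajectory_frame(self):
        """Long-format per-iteration parameter table (for convergence plots)."""
        import pandas as pd

        n_iter = self.trajectory["sigma2"].size
        data = {"iteration": np.arange(1, n_iter + 1)}
        beta = self.trajectory["beta"]
        for j in range(beta.shape[1]):
            data[f"beta_{j + 1}"] = beta[:, j]
        data["sigma2"] = self.trajectory["sigma2"]
        p_tr = self.trajectory["P"]
        g_tr = self.trajectory["G"]
        m = p_tr.shape[1]
        q = g_tr.shape[1]
        for a in range(m):
            for b in range(a, m):
                data[f"P_{a + 1}{b + 1}"] = p_tr[:, a, b]
        for a in range(q):
            for b in range(a, q):
                data[f"G_{a + 1}{b + 1}"] = g_tr[:, a, b]
        return pd.DataFrame(data)


def fit(
    dataset: Dataset,
    spec: DesignSpec,
    kinship: Kinship,
    settings: SAEMSettings,
    init: Optional[Theta] = None,
    designs: Optional[DesignMatrices] = None,
) -> FitResult:
    """Run SAEM: simulation, stochastic approximation, M-step, repeated.

    Fully reproducible: all randomness flows from one generator seeded with
    ``settings.seed``.  Raises on divergence with the iteration index.
    """
    if designs is None:
        designs = build_designs(dataset, spec)
    kinship.aligned_to(dataset)
    curve = spec.get_curve()
    rng = np.random.default_rng(settings.seed)
    n_v, q, m = kinship.n, designs.q, designs.m

    if init is None:
        theta, phi = initialize_theta(designs, curve)
    else:
        theta = init.copy()
        _, phi = initialize_theta(designs, curve)
    theta_init = theta.copy()
    u = np.zeros(q * n_v)
    k_inv = spd_inverse(kinship.K, "K")

    if settings.proposal_scale is not None:
        scales = np.broadcast_to(
            np.asarray(settings.proposal_scale, dtype=float), (m,)
        ).copy()
    else:
        scales = np.full(m, 1.0)

    n_iter = settings.n_iter
    traj = {
        "beta": np.empty((n_iter, designs.p)),
        "sigma2": np.empty(n_iter),
        "P": np.empty((n_iter, m, m)),
        "G": np.empty((n_iter, q, q)),
    }
    acceptance = np.empty((n_iter, m))
    stats: Optional[SAStats] = None

    for k in range(1, n_iter + 1):
        gamma = step_size(k, settings)
        phi, acc = mh_transition_phi(
            designs, curve, theta, u, phi, scales, settings.mh_inner, rng
        )
        acceptance[k - 1] = acc
        if k <= settings.n_burn:
            # Robbins-Monro tuning of the log proposal scales toward the
            # target acceptance; frozen after burn-in
            rate = min(0.5, 2.0 / np.sqrt(k))
            scales *= np.exp(rate * (acc - settings.adapt_target))
            scales = np.clip(scales, 1e-8, 1e8)
        u_mean, low = u_conditional(theta, kinship, designs, phi, return_chol=True)
        u_cov = linalg.cho_solve((low, True), np.eye(u_mean.size))
        z = rng.standard_normal(u_mean.size)
        u = u_mean + linalg.solve_triangular(low.T, z, lower=False)
        new_stats = conditional_statistics(designs, curve, phi, u_mean, u_cov, k_inv)
        stats = new_stats if stats is None else sa_update(stats, new_stats, gamma)
        theta = m_step(stats, designs, n_v, prev_theta=theta)
        if not theta.is_finite():
            raise NumericalError(
                f"SAEM diverged at iteration {k}: non-finite parameter update"
            )
        traj["beta"][k - 1] = theta.beta
        traj["sigma2"][k - 1] = theta.sigma2
        traj["P"][k - 1] = theta.P
        traj["G"][k - 1] = theta.G

    latent = LatentState(phi=phi, u=u, sa_stats=stats)
    return FitResult(
        theta=theta,
        trajectory=traj,
        acceptance=acceptance,
        latent=latent,
        settings=settings,
        theta_init=theta_init,
    )
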