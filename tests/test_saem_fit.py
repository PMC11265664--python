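"""SAEM machinery: schedule, SA updates, kernels, M-step, full fits."""

import numpy as np
import pytest
from scipy import optimize

from conftest import make_instance
from growsaem import (
    Dataset,
    Kinship,
    PlantRecord,
    SAEMSettings,
    Theta,
    build_designs,
    design_from_terms,
    fit,
    get_preset,
    simulate_dataset,
    step_size,
)
from growsaem.model_core import spd_inverse
from growsaem.saem_fit import (
    SAStats,
    draw_statistics,
    m_step,
    mh_transition_phi,
    q_objective,
    sa_update,
    sample_u,
)


class TestStepSize:
    def test_burn_in_is_unit(self):
        s = SAEMSettings(n_iter=1500, n_burn=1300, seed=0)
        assert all(step_size(k, s) == 1.0 for k in (1, 650, 1300))

    def test_reference_schedule_value(self):
        # (k - n_burn)^(-2/3) at k = n_burn + 8 gives 8^(-2/3) = 1/4
        s = SAEMSettings(n_iter=1500, n_burn=1300, seed=0)
        assert step_size(1308, s) == pytest.approx(0.25, abs=1e-15)
        assert step_size(1301, s) == 1.0  # continuous at the phase change

    def test_nonincreasing_after_burn_in(self):
        s = SAEMSettings(n_iter=200, n_burn=100, seed=0)
        gammas = [step_size(k, s) for k in range(101, 201)]
        assert all(a >= b for a, b in zip(gammas, gammas[1:]))

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            SAEMSettings(n_iter=10, n_burn=5, sa_exponent=0.4, seed=0)


class TestSAUpdate:
    def _stats(self, value):
        return SAStats(
            rss=value,
            s1=np.full((1, 1), value),
            s2=np.full((1, 1, 1), value),
            scatter=np.full((1, 1), value),
        )

    def test_unit_step_replaces(self):
        out = sa_update(self._stats(3.0), self._stats(9.0), 1.0)
        assert out.rss == 9.0

    def test_half_step_averages(self):
        out = sa_update(self._stats(0.0), self._stats(4.0), 0.5)
        assert out.rss == 2.0
        assert out.scatter[0, 0] == 2.0

    def test_converges_to_constant_target(self):
        stats = self._stats(0.0)
        for k in range(1, 200):
            stats = sa_update(stats, self._stats(7.0), k ** (-2 / 3))
        assert stats.rss == pytest.approx(7.0, rel=1e-3)


def _theta_to_vector(theta):
    m, q = theta.P.shape[0], theta.G.shape[0]
    lp = np.linalg.cholesky(theta.P)
    lg = np.linalg.cholesky(theta.G)
    parts = [theta.beta, [np.log(theta.sigma2)]]
    for mat, dim in ((lp, m), (lg, q)):
        tril = mat[np.tril_indices(dim)]
        diag_pos = np.cumsum(np.arange(1, dim + 1)) - 1
        tril[diag_pos] = np.log(np.diag(mat))
        parts.append(tril)
    return np.concatenate(parts)


def _vector_to_theta(vec, p, m, q):
    beta = vec[:p]
    sigma2 = np.exp(vec[p])
    at = p + 1

    def unpack(dim):
        nonlocal at
        size = dim * (dim + 1) // 2
        tril = vec[at : at + size].copy()
        at += size
        low = np.zeros((dim, dim))
        low[np.tril_indices(dim)] = tril
        np.fill_diagonal(low, np.exp(np.diag(low)))
        return low @ low.T

    return Theta(beta=beta, sigma2=sigma2, P=unpack(m), G=unpack(q))


class TestMStep:
    def test_single_variety_scatter_is_outer_product(self):
        inst = make_instance(1, 4, seed=1)
        designs, kin = inst["designs"], inst["kinship"]
        kin_i = Kinship(np.eye(1), kin.varieties[:1])
        u = inst["rng"].standard_normal(designs.q)
        stats = draw_statistics(
            designs, inst["spec"].get_curve(), inst["phi"], u, np.eye(1)
        )
        theta = m_step(stats, designs, 1)
        np.testing.assert_allclose(theta.G, np.outer(u, u), atol=1e-12)

    def test_identity_kinship_scatter_is_mean_outer(self):
        inst = make_instance(4, 3, seed=2)
        designs = inst["designs"]
        q, n_v = designs.q, 4
        u = inst["rng"].standard_normal(n_v * q)
        stats = draw_statistics(
            designs, inst["spec"].get_curve(), inst["phi"], u, np.eye(n_v)
        )
        theta = m_step(stats, designs, n_v)
        u_mat = u.reshape(n_v, q)
        expected = sum(np.outer(u_mat[v], u_mat[v]) for v in range(n_v)) / n_v
        np.testing.assert_allclose(theta.G, expected, atol=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_varieties=2, plants_per_variety=3, curve="constant",
                 times=(1.0, 2.0), seed=5),
            dict(n_varieties=3, plants_per_variety=4, curve="logistic",
                 fixed_terms=("1", "x"), covariate_values=(0.0, 1.0), seed=6),
        ],
        ids=["constant-m1", "logistic-two-patterns"],
    )
    def test_closed_form_maximizes_q(self, kwargs):
        # the M-step arg-max agrees with a general-purpose numerical
        # optimizer of Q(theta) to 1e-4 relative
        inst = make_instance(**kwargs)
        designs, kin = inst["designs"], inst["kinship"]
        k_inv = spd_inverse(kin.K)
        u = inst["u"]
        stats = draw_statistics(
            designs, inst["spec"].get_curve(), inst["phi"], u, k_inv
        )
        theta_hat = m_step(stats, designs, kin.n)
        p, m, q = designs.p, designs.m, designs.q

        def neg_q(vec):
            return -q_objective(stats, _vector_to_theta(vec, p, m, q), designs, kin)

        start = _theta_to_vector(theta_hat) * 1.05 + 0.01
        res = optimize.minimize(
            neg_q, start, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 40000,
                     "maxfev": 40000},
        )
        res = optimize.minimize(neg_q, res.x, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        numeric = _vector_to_theta(res.x, p, m, q)
        np.testing.assert_allclose(numeric.beta, theta_hat.beta, rtol=1e-4, atol=1e-5)
        assert numeric.sigma2 == pytest.approx(theta_hat.sigma2, rel=1e-4)
        np.testing.assert_allclose(numeric.P, theta_hat.P, rtol=2e-4, atol=1e-6)
        np.testing.assert_allclose(numeric.G, theta_hat.G, rtol=2e-4, atol=1e-6)
        # and the closed form is at least as good in Q value
        assert q_objective(stats, theta_hat, designs, kin) >= -res.fun - 1e-8

    def test_zero_residual_floors_sigma2_with_warning(self):
        inst = make_instance(2, 2, seed=8)
        designs = inst["designs"]
        stats = draw_statistics(
            designs, inst["spec"].get_curve(), inst["phi"], inst["u"],
            spd_inverse(inst["kinship"].K),
        )
        stats = SAStats(rss=0.0, s1=stats.s1, s2=stats.s2, scatter=stats.scatter)
        with pytest.warns(RuntimeWarning, match="floor"):
            theta = m_step(stats, designs, inst["kinship"].n)
        assert theta.sigma2 == pytest.approx(1e-12)


class TestSimulationKernels:
    def test_sample_u_moments_match_conditional(self):
        from growsaem import u_conditional

        inst = make_instance(2, 2, seed=3)
        designs = inst["designs"]
        mean, cov = u_conditional(
            inst["theta"], inst["kinship"], designs, inst["phi"]
        )
        rng = np.random.default_rng(99)
        draws = np.array([
            sample_u(inst["theta"], inst["kinship"], designs, inst["phi"], rng)
            for _ in range(5000)
        ])
        se = np.sqrt(np.diag(cov) / len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3 * se)
        emp_cov = np.cov(draws.T)
        # covariance entries: 3 approximate MC standard errors
        cov_se = np.sqrt(
            (np.outer(np.diag(cov), np.diag(cov)) + cov**2) / len(draws)
        )
        assert np.all(np.abs(emp_cov - cov) < 3.5 * cov_se)

    def test_sample_u_reproducible(self):
        inst = make_instance(2, 2, seed=3)
        designs = inst["designs"]
        a = sample_u(inst["theta"], inst["kinship"], designs, inst["phi"],
                     np.random.default_rng(7))
        b = sample_u(inst["theta"], inst["kinship"], designs, inst["phi"],
                     np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def _linear_instance(self, sigma2):
        spec = design_from_terms("constant", ["1"], ["1"])
        plants = [
            PlantRecord(f"p{i}", "v1", {}, np.array([1.0, 2.0, 3.0]),
                        np.array([4.8, 5.1, 5.4]))
            for i in range(2)
        ]
        ds = Dataset(plants, {"v1": 0})
        designs = build_designs(ds, spec)
        theta = Theta(np.array([5.0]), sigma2, np.array([[0.5]]), np.eye(1))
        return spec, designs, theta

    def test_chain_matches_closed_form_posterior(self):
        # constant curve: phi_i | u, y is exactly Gaussian with
        # precision n_i / sigma2 + 1/P
        spec, designs, theta = self._linear_instance(sigma2=0.8)
        u = np.array([0.3])
        prior_mean = designs.phi_mean(theta.beta, u)[:, 0]
        prec = 3 / theta.sigma2 + 1 / theta.P[0, 0]
        post_var = 1 / prec
        post_mean = (
            designs.values.sum(axis=1) / theta.sigma2 + prior_mean / theta.P[0, 0]
        ) * post_var
        rng = np.random.default_rng(17)
        phi = prior_mean[:, None].copy()
        n_steps = 40000
        chain = np.empty((n_steps, 2))
        for s in range(n_steps):
            phi, _ = mh_transition_phi(
                designs, spec.get_curve(), theta, u, phi,
                np.array([0.8]), 1, rng,
            )
            chain[s] = phi[:, 0]
        chain = chain[2000:]
        # conservative effective-sample-size allowance for autocorrelation
        n_eff = len(chain) / 20
        se_mean = np.sqrt(post_var / n_eff)
        assert np.all(np.abs(chain.mean(axis=0) - post_mean) < 3 * se_mean)
        assert np.all(
            np.abs(chain.var(axis=0) - post_var) < 3 * post_var * np.sqrt(2 / n_eff)
        )

    def test_flat_likelihood_recovers_prior(self):
        # sigma2 -> infinity: the stationary distribution is the prior
        spec, designs, theta = self._linear_instance(sigma2=1e8)
        u = np.array([-0.2])
        prior_mean = designs.phi_mean(theta.beta, u)[:, 0]
        rng = np.random.default_rng(23)
        phi = prior_mean[:, None].copy()
        n_steps = 40000
        chain = np.empty((n_steps, 2))
        for s in range(n_steps):
            phi, _ = mh_transition_phi(
                designs, spec.get_curve(), theta, u, phi, np.array([1.0]), 1, rng
            )
            chain[s] = phi[:, 0]
        chain = chain[2000:]
        n_eff = len(chain) / 20
        p_var = theta.P[0, 0]
        assert np.all(
            np.abs(chain.mean(axis=0) - prior_mean) < 3 * np.sqrt(p_var / n_eff)
        )
        assert np.all(
            np.abs(chain.var(axis=0) - p_var) < 3 * p_var * np.sqrt(2 / n_eff)
        )

    def test_non_finite_target_identifies_plant(self):
        spec, designs, theta = self._linear_instance(sigma2=1.0)
        phi = np.array([[np.nan], [5.0]])
        with pytest.raises(Exception, match="plant index 0"):
            mh_transition_phi(
                designs, spec.get_curve(), theta, np.zeros(1), phi,
                np.array([0.5]), 1, np.random.default_rng(0),
            )


class TestFit:
    def test_near_noiseless_recovers_fixed_effects(self):
        preset = get_preset(
            "scenario2", n_varieties=8, n_plants=32, n_obs=10, n_markers=400,
            theta=Theta(
                beta=np.array([50.0, 13.0]),
                sigma2=1e-4,
                P=np.diag([0.01, 0.001]),
                G=np.diag([0.02, 0.002]),
            ),
        )
        sim = simulate_dataset(preset, seed=5)
        res = fit(
            sim.dataset, sim.spec, sim.kinship,
            SAEMSettings(n_iter=150, n_burn=120, seed=9),
        )
        np.testing.assert_allclose(res.theta.beta, [50.0, 13.0], rtol=1e-2)

    def test_same_seed_is_bit_identical(self):
        preset = get_preset("scenario2", n_varieties=6, n_plants=18, n_obs=6,
                            n_markers=200)
        sim = simulate_dataset(preset, seed=2)
        settings = SAEMSettings(n_iter=60, n_burn=40, seed=77)
        a = fit(sim.dataset, sim.spec, sim.kinship, settings)
        b = fit(sim.dataset, sim.spec, sim.kinship, settings)
        for key in a.trajectory:
            np.testing.assert_array_equal(a.trajectory[key], b.trajectory[key])
        np.testing.assert_array_equal(a.latent.u, b.latent.u)

    def test_refining_phase_stabilizes_trajectory(self):
        preset = get_preset("scenario2", n_varieties=10, n_plants=40, n_obs=10,
                            n_markers=300)
        sim = simulate_dataset(preset, seed=3)
        res = fit(
            sim.dataset, sim.spec, sim.kinship,
            SAEMSettings(n_iter=260, n_burn=160, seed=4),
        )
        beta1 = res.trajectory["beta"][:, 0]
        burn_sd = beta1[80:160].std()
        refine_sd = beta1[-60:].std()
        assert refine_sd < burn_sd

    def test_acceptance_rates_near_target_after_adaptation(self):
        preset = get_preset("scenario2", n_varieties=8, n_plants=24, n_obs=8,
                            n_markers=200)
        sim = simulate_dataset(preset, seed=6)
        res = fit(
            sim.dataset, sim.spec, sim.kinship,
            SAEMSettings(n_iter=200, n_burn=160, seed=8, adapt_target=0.35),
        )
        late = res.acceptance[150:160].mean(axis=0)
        assert np.all(np.abs(late - 0.35) < 0.15)
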