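# growsaem

Kinship-aware nonlinear mixed-effects modelling of plant growth curves,
fitted by stochastic approximation EM (SAEM).

## The problem

High-throughput phenotyping (UAV imagery, proximal sensing) yields repeated
height or biomass measurements for hundreds of varieties grown under
different treatments. Breeders want to separate, within a single model, the
genetic and non-genetic determinants of growth-curve shape: which varieties
reach taller plateaus, which grow faster, how strongly irrigation response
is inherited — and to predict growth for varieties or environments that
were never observed, using genome-wide relatedness.

`growsaem` implements a two-stratum nonlinear mixed-effects model specified
at the *plant* level:

```
y_ij  = g(φ_i, t_ij) + ε_ij,          ε_ij ~ N(0, σ²)
φ_i   = X_i β + Z_i u + p_i,          p_i  ~ N(0, P),   u ~ N(0, K ⊗ G)
```

where `g` is a growth curve (logistic `A / (1 + exp(-γ(t - x)))`,
asymptotic regression `φ₁(1 - exp(-exp(φ₂) t))`, or any user-registered
curve), `φ_i ∈ R^m` are plant-level growth parameters, `β` fixed covariate
effects, `u` stacks one `q`-vector of genetic effects per variety with
covariance `K ⊗ G` (`K` the genomic relationship matrix between varieties,
`G` the genetic covariance of the effects), and `p_i` are plant effects
with covariance `P`. The ratio `G_kk / (G_kk + P_kk)` is reported as a
heritability proxy per growth trait.

Neither the likelihood nor the posterior of `u` is tractable, so both
inference problems run on SAEM with a Metropolis-within-Gibbs simulation
step:

* **parameter estimation** — maximum likelihood for θ = (β, σ², P, G):
  random-walk Metropolis on each `φ_i` targeting `p(φ_i | u, y_i)`, an
  exact Gaussian draw of `u | φ`, stochastic approximation of the
  complete-data sufficient statistics with step sizes `γ_k = 1` during
  burn-in and `(k − n_burn)^(−2/3)` after, and closed-form M-steps;
* **genetic-effect prediction** — maximum a posteriori `û = argmax p(u | y, θ̂)`
  by a second SAEM run with `φ` as the latent variable.

Prediction plugs the estimates into the model mean, `φ̂_i = X_i β̂ + Z_i û`,
`ŷ_i(t) = g(φ̂_i, t)`; effects of varieties never observed are deduced from
the kinship matrix by Gaussian conditioning. A cross-validation harness
covers the three standard genomic-prediction schemes: cv0 (unseen
environment), cv1 (unseen varieties), cv2 (unseen variety × environment
combinations).

A scenario simulator generates all inputs — marker genotypes,
VanRaden GRM, and phenotypes — so every analysis in the package runs
without external data.

## Worked example

Simulate the sparse-sampling scenario (logistic curve, 50 varieties, 200
plants, 10 observations per plant on [1, 45]; generating values μ_A = 50,
μ_x = 13, σ² = 4, P = diag(6, 0.4), G = diag(25, 1.5)) and re-estimate:

```python
import numpy as np
import growsaem as gs

preset = gs.get_preset("scenario2", n_varieties=50, n_plants=200)
sim = gs.simulate_dataset(preset, seed=1)
result = gs.fit(sim.dataset, sim.spec, sim.kinship,
                gs.SAEMSettings(n_iter=600, n_burn=500, seed=101))
theta = result.theta
print("beta      ", np.round(theta.beta, 3))
print("sigma2    ", round(theta.sigma2, 3))
print("P diag    ", np.round(np.diag(theta.P), 3))
print("G diag    ", np.round(np.diag(theta.G), 3))

report = gs.heritability(theta.G, theta.P, [(0, 0), (1, 1)],
                         names=["h_A", "h_x"])
effects = gs.map_u(sim.dataset, sim.spec, sim.kinship, theta,
                   gs.map_settings(seed=102, n_iter=400, n_burn=320))
u_hat = effects.effects_matrix(sim.spec.q)
u_true = sim.u.reshape(-1, 2)
print("corr(u_hat, u_true) per trait:",
      [round(float(np.corrcoef(u_hat[:, j], u_true[:, j])[0, 1]), 2)
       for j in range(2)])
```

Output:

```
beta       [50.132 12.986]
sigma2     3.92
P diag     [6.529 0.544]
G diag     [18.216  1.229]
corr(u_hat, u_true) per trait: [0.95, 0.95]
```

The fixed effects and residual variance are recovered to within a fraction
of a percent; the variance components carry the sampling noise expected of
a single 50-variety replicate (averaging replicate fits centers them on the
truth — see the reproduction script below). The heritability report on this
fit gives `h_A = 0.74`, `h_x = 0.69`, and the MAP genetic effects correlate
0.95 with the generating ones on both traits.

The same pipeline is available from the shell:

```bash
growsaem simulate --preset scenario2 --seed 1 --out sim/
growsaem fit --phenotypes sim/phenotypes.csv --kinship sim/kinship.csv \
             --config config.yaml --seed 101 --out fit/
growsaem predict-effects --phenotypes sim/phenotypes.csv \
             --kinship sim/kinship.csv --config config.yaml \
             --theta fit/theta.yaml --seed 102 --out effects.csv
growsaem cv --scenario cv2 --folds 5 --reps 4 --env x ...
growsaem herit --theta fit/theta.yaml
```

Every run writes a plain-text log (seed, config hash, versions); identical
seeds reproduce outputs byte for byte.

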